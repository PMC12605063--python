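"""Idealised spherical 64-channel extended 10-20 montage.

Positions are constructed geometrically on the unit sphere: midline
sites sit on the nasion-inion great circle, ring sites (7/8, Fp, O) on
the equatorial head circumference, 9/10 sites 18 degrees below it, and
inner sites on great-circle arcs between the midline and the ring.
Good enough for smooth topographies and distance-based adjacency; no
claim of digitised-cap accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MontageSpec", "standard_montage", "adjacency_matrix"]

#: BrainProducts-style 64-channel layout recorded against FCz.
CHANNELS_64 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
]

# per-row percentage along the nasion-inion midline arc (nasion = 0)
_ROW_PCT = {
    "Fp": 10, "AF": 20, "F": 30, "FT": 40, "FC": 40, "C": 50, "T": 50,
    "TP": 60, "CP": 60, "P": 70, "PO": 80, "O": 90,
}
# ring rows use the temporal letter for their equatorial anchor
_RING_ROW = {"FC": "FT", "CP": "TP", "C": "T"}
# lateral fraction along the midline->ring arc for inner site numbers
_LATERAL = {1: 0.25, 2: 0.25, 3: 0.5, 4: 0.5, 5: 0.75, 6: 0.75}


def _midline_point(pct: float) -> np.ndarray:
    # polar angle from vertex; ring (10%/90%) maps to the equator
    alpha = np.deg2rad((50.0 - pct) / 40.0 * 90.0)
    return np.array([0.0, np.sin(alpha), np.cos(alpha)])


def _ring_point(pct: float, right: bool, dip_deg: float = 0.0) -> np.ndarray:
    # circumferential fraction is half the midline row percentage
    # (F7 sits 15% around the ring while Fz is 30% along the midline)
    az = np.deg2rad(pct * 1.8)  # 0 = nose, pi = inion
    sign = 1.0 if right else -1.0
    dip = np.deg2rad(dip_deg)
    return np.array(
        [sign * np.sin(az) * np.cos(dip), np.cos(az) * np.cos(dip), -np.sin(dip)]
    )


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-9:
        return a
    return (np.sin((1 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)


def _parse(name: str) -> tuple[str, str]:
    i = len(name)
    while i > 0 and (name[i - 1].isdigit() or name[i - 1] == "z"):
        i -= 1
    return name[:i], name[i:]


def channel_position(name: str) -> np.ndarray:
    row, suffix = _parse(name)
    pct = float(_ROW_PCT[row])
    if suffix == "z":
        return _midline_point(pct)
    num = int(suffix)
    right = num % 2 == 0
    ring_row = _RING_ROW.get(row, row)
    ring_pct = float(_ROW_PCT[ring_row])
    if num in (9, 10):
        return _ring_point(ring_pct, right, dip_deg=18.0)
    if num in (7, 8) or row in ("Fp", "O"):
        # Fp1/2 and O1/2 sit on the equatorial ring next to the midline
        return _ring_point(ring_pct, right)
    frac = _LATERAL[num] if row != "AF" else 0.5
    return _slerp(_midline_point(pct), _ring_point(ring_pct, right), frac)


@dataclass(frozen=True)
class MontageSpec:
    """Channel names with unit-sphere positions and the reference label."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm
    reference: str = "FCz"

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def great_circle_distances(self) -> np.ndarray:
        """Pairwise arc distances (radians) on the unit sphere."""
        cosine = np.clip(self.positions @ self.positions.T, -1.0, 1.0)
        return np.arccos(cosine)


def standard_montage() -> MontageSpec:
    pos = np.stack([channel_position(c) for c in CHANNELS_64])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return MontageSpec(channel_names=tuple(CHANNELS_64), positions=pos)


def adjacency_matrix(montage: MontageSpec, target_neighbours: int = 6) -> np.ndarray:
    """Boolean channel adjacency from a great-circle distance cutoff.

    The cutoff is the median over channels of the distance to their
    ``target_neighbours``-th nearest neighbour, so the median degree is
    approximately ``target_neighbours``.
    """
    d = montage.great_circle_distances()
    np.fill_diagonal(d, np.inf)
    kth = np.sort(d, axis=1)[:, target_neighbours - 1]
    cutoff = float(np.median(kth)) * 1.001
    adj = d <= cutoff
    return adj | adj.T
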