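"""Run configuration and the end-to-end pipeline runner.

Stages: simulate (or ingest) -> preprocess -> GFP/window selection ->
cluster contrasts -> band amplitude/DFA -> behavioural statistics ->
accuracy GLMM.  All randomness flows from the named seeds in the config;
a structured JSON report (with the resolved config embedded) plus TSV
tables are written to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import band_dynamics, behav_stats, chord_stimuli, erp_stats, glmm, synth_eeg
from .montage import adjacency_matrix, standard_montage
from .preprocess import PreprocessConfig, preprocess_pipeline

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

REQUIRED_FIELDS = ("seed", "n_subjects")


@dataclass(frozen=True)
class RunConfig:
    seed: int
    n_subjects: int
    sample_rate_hz: float = 500.0
    downsample_to_hz: float = 250.0
    repetitions: int = 5
    n_neutral: int = 14
    isi_range_ms: tuple[float, float] = (200.0, 300.0)
    n_permutations: int = 800
    alpha: float = 0.05
    window_half_width_ms: float = 10.0
    n_gfp_peaks: int = 3
    dfa_range_s: tuple[float, float] = (5.0, 50.0)
    dfa_n_windows: int = 10
    run_ica: bool = False
    erp_gain: float = 1.0
    noise_gain: float = 1.0
    glmm_band: str = "gamma"
    glmm_predictor: str = "amplitude"  # or "dfa"
    fisher_n_sim: int = 100_000
    contrasts: tuple[tuple[str, str], ...] = (
        ("dissonant", "neutral"),
        ("consonant", "neutral"),
        ("consonant", "dissonant"),
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 < self.downsample_to_hz < self.sample_rate_hz:
            raise ValueError("downsample rate must lie in (0, sample_rate)")
        if self.glmm_predictor not in ("amplitude", "dfa"):
            raise ValueError("glmm_predictor must be 'amplitude' or 'dfa'")

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        for name in REQUIRED_FIELDS:
            if name not in payload:
                raise ValueError(f"config is missing required field {name!r}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        payload = dict(payload)
        for tup_field in ("isi_range_ms", "dfa_range_s", "contrasts"):
            if tup_field in payload and isinstance(payload[tup_field], list):
                val = payload[tup_field]
                payload[tup_field] = (
                    tuple(tuple(v) for v in val) if tup_field == "contrasts"
                    else tuple(val)
                )
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _content_hash(payload) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the report bundle; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}
    report["config_hash"] = _content_hash(report["config"])
    stage = "setup"
    try:
        seeds = np.random.SeedSequence(config.seed).spawn(4)
        montage = standard_montage()
        truth = synth_eeg.GroundTruth(sample_rate=config.sample_rate_hz).scaled(
            erp_gain=config.erp_gain, noise_gain=config.noise_gain
        )
        stimuli = chord_stimuli.build_stimulus_set(n_neutral=config.n_neutral)

        stage = "simulate+preprocess"
        pp_cfg = PreprocessConfig(
            downsample_to_hz=config.downsample_to_hz, run_ica=config.run_ica
        )
        sub_seeds = seeds[0].spawn(config.n_subjects)
        overall_avgs = []
        band_rows = []
        times_ms = None
        epoch_store = []
        for s in range(config.n_subjects):
            sched = chord_stimuli.make_schedule(
                stimuli,
                repetitions=config.repetitions,
                seed=int(sub_seeds[s].generate_state(1)[0] % 2**31),
                isi_range_ms=config.isi_range_ms,
            )
            rec = synth_eeg.simulate_recording(montage, sched, truth, sub_seeds[s])
            epochs, info = preprocess_pipeline(rec, pp_cfg)
            times_ms = epochs.times_ms
            overall_avgs.append(erp_stats.grand_average(epochs))
            epoch_store.append(epochs)
            cont = info["continuous"]  # preprocessed continuous signal for DFA
            stats_df = band_dynamics.recording_band_stats(
                cont.data, cont.channel_names, cont.sfreq,
                window_range_s=config.dfa_range_s,
                n_windows=config.dfa_n_windows,
            )
            stats_df.insert(0, "subject", f"S{s:02d}")
            band_rows.append(stats_df)
            log.info("subject %d/%d processed", s + 1, config.n_subjects)

        stage = "gfp"
        # bad-channel exclusion may differ across subjects: align on the
        # common channel set before any cross-subject aggregation
        common = [
            c for c in montage.channel_names
            if all(c in e.channel_names for e in epoch_store)
        ]
        report["common_channels"] = len(common)
        sel_idx = [
            [e.channel_names.index(c) for c in common] for e in epoch_store
        ]
        grand = np.mean(
            [avg[idx] for avg, idx in zip(overall_avgs, sel_idx)], axis=0
        )
        curve = erp_stats.gfp_curve(grand, times_ms)
        windows = erp_stats.select_windows(
            curve, n_peaks=config.n_gfp_peaks,
            half_width_ms=config.window_half_width_ms,
        )
        report["gfp_windows_ms"] = [list(w) for w in windows]

        stage = "cluster_contrasts"
        keep = [montage.channel_names.index(c) for c in common]
        adjacency = adjacency_matrix(montage)[np.ix_(keep, keep)]
        perm_seed = int(seeds[1].generate_state(1)[0] % 2**31)
        cluster_rows = []
        for window in windows:
            for cond_a, cond_b in config.contrasts:
                maps_a = np.stack(
                    [erp_stats.window_mean_map(e, cond_a, window)[idx]
                     for e, idx in zip(epoch_store, sel_idx)]
                )
                maps_b = np.stack(
                    [erp_stats.window_mean_map(e, cond_b, window)[idx]
                     for e, idx in zip(epoch_store, sel_idx)]
                )
                results = erp_stats.cluster_permutation(
                    maps_a, maps_b, adjacency,
                    channel_names=tuple(common),
                    n_perm=config.n_permutations,
                    alpha=config.alpha,
                    seed=perm_seed,
                    contrast=f"{cond_a}:{cond_b}",
                    window_ms=tuple(window),
                )
                for r in results:
                    cluster_rows.append(
                        {
                            "contrast": r.contrast,
                            "window_ms": f"{window[0]:g}-{window[1]:g}",
                            "n_channels": len(r.channels),
                            "channels": ",".join(r.channels),
                            "mass": r.mass,
                            "p": r.p_value,
                            "significant": r.p_value < config.alpha,
                        }
                    )
        clusters_df = pd.DataFrame(cluster_rows)
        clusters_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
        report["clusters"] = cluster_rows

        stage = "band_dynamics"
        bands_df = pd.concat(band_rows, ignore_index=True)
        bands_df.to_csv(out / "bands.tsv", sep="\t", index=False)
        metric = "amplitude_uv" if config.glmm_predictor == "amplitude" else "dfa_exponent"
        per_subject = (
            bands_df[bands_df["band"] == config.glmm_band]
            .groupby("subject")[metric]
            .mean()
        )

        stage = "behaviour"
        sched0 = chord_stimuli.make_schedule(
            stimuli, repetitions=config.repetitions,
            seed=int(seeds[2].generate_state(1)[0] % 2**31),
            isi_range_ms=config.isi_range_ms,
        )
        xs = per_subject.to_numpy()
        xs_std = (xs - xs.mean()) / (xs.std() if xs.std() > 0 else 1.0)
        trials = synth_eeg.simulate_trial_tables(sched0, truth, xs_std, seeds[3])
        synth_eeg.write_trial_table(out / "trials.tsv", trials)
        report["behaviour"] = behav_stats.behaviour_report(
            trials, n_sim=config.fisher_n_sim,
            seed=int(seeds[2].generate_state(2)[1] % 2**31),
        )

        stage = "glmm"
        neural_map = {
            f"S{i:02d}": float(x) for i, x in enumerate(xs_std)
        }
        full = glmm.fit_mixed_logit(trials, neural=neural_map, spec=glmm.GLMMSpec())
        reduced = glmm.fit_mixed_logit(
            trials, neural=neural_map,
            spec=glmm.GLMMSpec(include_interactions=False),
        )
        chi2, df, p = glmm.likelihood_ratio_test(full, reduced)
        ors = glmm.odds_ratio_table(full)
        summary = full.summary().join(ors)
        summary.to_csv(out / "glmm.tsv", sep="\t")
        report["glmm"] = {
            "band": config.glmm_band,
            "predictor": config.glmm_predictor,
            "fixed_effects": json.loads(summary.to_json(orient="index")),
            "variance_components": full.variance_components,
            "converged": full.converged,
            "lrt": {"chi2": chi2, "df": df, "p": p},
        }
    except Exception as err:
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
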