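"""End-to-end orchestration: simulate/ingest -> phases -> DBI + DTF -> compare.

A :class:`PipelineConfig` (YAML-serializable) fixes every analysis constant:
band definitions, DBI windowing (25 s, 50% overlap, Fourier order 2,
propagation constant 0.2, 100 inter-subject surrogates) and DTF settings
(60-s windows, MVAR order 7, alpha = 0.05, band (0.05, 2) Hz). A single
global seed fans out deterministically to per-stage, per-subject subseeds via
``numpy.random.SeedSequence.spawn``, so a rerun with the same config
reproduces every numeric output bit for bit.

Because ridge extraction is a per-channel operation, inter-subject surrogate
ensembles reuse the ridges already extracted from each subject's channels;
recombining phases across subjects is exactly equivalent to extracting
ridges from recombined recordings.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cardionet import dbi as dbi_mod
from cardionet import dtf as dtf_mod
from cardionet import stats as stats_mod
from cardionet.preprocess import RidgeCurve, extract_component_phase
from cardionet.recording import MultiChannelRecording, read_recording, write_recording
from cardionet.synthetic import (
    CARDIAC_BAND,
    RESPIRATORY_BAND,
    make_intersubject_surrogates,
    simulate_cohort,
)

logger = logging.getLogger("cardionet")

# DBI pair definitions: (pair name, oscillator-1 phase key, oscillator-2 phase key)
# phase keys: cardiac ridge from ECG ("ecg"), respiratory ridge ("breathing"),
# cardiac ridge from the perfusion signal ("pulse")
DBI_PAIRS = (
    ("Lungs-Pulse", "breathing", "pulse"),
    ("Lungs-Heart", "breathing", "ecg"),
    ("Heart-Pulse", "ecg", "pulse"),
)

# channel indices in the recording: ecg=0, breathing=1, perfusion=2
_DTF_MEASURE_INDEX = {
    "ssDTF_perf->bre": (1, 2),
    "ssDTF_bre->perf": (2, 1),
    "ssDTF_ECG->bre": (1, 0),
    "ssDTF_bre->ECG": (0, 1),
    "ssDTF_perf->ECG": (0, 2),
    "ssDTF_ECG->perf": (2, 0),
}
# directionality rows: (measure, forward strength, reverse strength)
_DTF_D_ROWS = {
    "d_bre,perf": ("ssDTF_bre->perf", "ssDTF_perf->bre"),
    "d_bre,ECG": ("ssDTF_bre->ECG", "ssDTF_ECG->bre"),
    "d_ECG,perf": ("ssDTF_ECG->perf", "ssDTF_perf->ECG"),
}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "run"
    input_dir: str | None = None  # ingest recordings instead of simulating
    n_subjects_control: int = 10
    n_subjects_t1d: int = 10
    duration: float = 300.0
    sampling_rate: float = 250.0
    coupling_control: float | None = None  # None -> group preset
    coupling_t1d: float | None = None
    cardiac_band: tuple[float, float] = CARDIAC_BAND
    respiratory_band: tuple[float, float] = RESPIRATORY_BAND
    analysis_rate: float = 50.0
    dbi_window: float = 25.0
    dbi_overlap: float = 0.5
    dbi_order: int = 2
    dbi_pw: float = 0.2
    n_surrogates: int = 100
    dtf_window: float = 60.0
    dtf_order: int = 7
    dtf_alpha: float = 0.05
    dtf_band: tuple[float, float] = (0.05, 2.0)
    dtf_n_null: int = 100
    comparison_level: str = "window"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("cardiac_band", "respiratory_band", "dtf_band"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("cardiac_band", "respiratory_band", "dtf_band"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _subject_phases(
    rec: MultiChannelRecording, config: PipelineConfig
) -> dict[str, RidgeCurve]:
    """Extract the three component ridges of one subject."""
    return {
        "ecg": extract_component_phase(
            rec.channel("ecg"), rec.sampling_rate, config.cardiac_band, config.analysis_rate
        ),
        "breathing": extract_component_phase(
            rec.channel("breathing"), rec.sampling_rate, config.respiratory_band, config.analysis_rate
        ),
        "pulse": extract_component_phase(
            rec.channel("perfusion"), rec.sampling_rate, config.cardiac_band, config.analysis_rate
        ),
    }


def _run_dbi_pair(
    phases: dict[str, RidgeCurve], key1: str, key2: str, config: PipelineConfig
) -> list[dbi_mod.CouplingWindowResult]:
    return dbi_mod.run_dbi(
        phases[key1],
        phases[key2],
        window=config.dbi_window,
        overlap=config.dbi_overlap,
        order=config.dbi_order,
        pw=config.dbi_pw,
    )


def dbi_surrogate_thresholds(
    phases_by_subject: dict[str, dict[str, RidgeCurve]],
    config: PipelineConfig,
    seed: int,
) -> dict[str, dbi_mod.SurrogateThresholds]:
    """Per-pair, per-direction thresholds from inter-subject surrogates.

    Each surrogate assigns the ECG, breathing and perfusion ridges to three
    distinct subjects (triplets sampled without replacement from the
    enumerated valid set), then runs the windowed inference on each pair of
    now-independent phases. The threshold is the median strength over all
    surrogate windows, per pair and direction.
    """
    ids = sorted(phases_by_subject)
    if len(ids) < 3:
        raise ValueError("need at least 3 subjects for inter-subject surrogates")
    triplets = list(itertools.permutations(range(len(ids)), 3))
    n_sur = min(config.n_surrogates, len(triplets))
    if config.n_surrogates > len(triplets):
        logger.warning(
            "requested %d surrogates, only %d unique triplets; using all",
            config.n_surrogates, len(triplets),
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(triplets), size=n_sur, replace=False)
    per_pair: dict[str, list[list[dbi_mod.CouplingWindowResult]]] = {
        name: [] for name, _, _ in DBI_PAIRS
    }
    source_key = {"ecg": 0, "breathing": 1, "pulse": 2}
    for idx in chosen:
        trip = triplets[idx]
        mix = {
            key: phases_by_subject[ids[trip[pos]]][key] for key, pos in source_key.items()
        }
        for name, k1, k2 in DBI_PAIRS:
            per_pair[name].append(_run_dbi_pair(mix, k1, k2, config))
    return {name: dbi_mod.surrogate_thresholds(res) for name, res in per_pair.items()}


def collect_dbi_measures(
    results_by_subject: dict[str, dict[str, list[dbi_mod.CouplingWindowResult]]],
) -> dict[str, dict[str, np.ndarray]]:
    """Window-level values per DBI measure, keeping only significant windows.

    Strengths contribute where their own direction passes the surrogate
    threshold; directionality contributes only where both directions pass.
    """
    pair_measures = {
        "Lungs-Pulse": ("s_bre->pulse", "s_pulse->bre", "d_bre,pulse"),
        "Lungs-Heart": ("s_bre->ECG", "s_ECG->bre", "d_bre,ECG"),
        "Heart-Pulse": ("s_ECG->pulse", "s_pulse->ECG", "d_ECG,pulse"),
    }
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in stats_mod.DBI_MEASURES}
    for subject, by_pair in results_by_subject.items():
        for pair, (m12, m21, md) in pair_measures.items():
            res = by_pair[pair]
            out[m12][subject] = np.array([w.s_1to2 for w in res if w.significant_1to2])
            out[m21][subject] = np.array([w.s_2to1 for w in res if w.significant_2to1])
            out[md][subject] = np.array(
                [
                    w.d
                    for w in res
                    if w.significant_1to2 and w.significant_2to1 and w.d is not None
                ]
            )
    return out


def collect_dtf_measures(
    results_by_subject: dict[str, list[dtf_mod.DTFResult]],
) -> dict[str, dict[str, np.ndarray]]:
    """Window-level ssDTF band means and directionality per DTF measure."""
    out: dict[str, dict[str, np.ndarray]] = {m: {} for m in stats_mod.DTF_MEASURES}
    for subject, windows in results_by_subject.items():
        per_meas = {m: [] for m in stats_mod.DTF_MEASURES}
        for res in windows:
            ss = {m: res.ss_band_mean[idx] for m, idx in _DTF_MEASURE_INDEX.items()}
            for m, v in ss.items():
                if not np.isnan(v):
                    per_meas[m].append(float(v))
            for m, (fwd, rev) in _DTF_D_ROWS.items():
                d = dtf_mod.dtf_directionality(ss[fwd], ss[rev])
                if d is not None:
                    per_meas[m].append(d)
        for m, vals in per_meas.items():
            out[m][subject] = np.array(vals, dtype=float)
    return out


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write all artifacts under ``config.out_dir``.

    Returns the run directory. Stages: simulate (or ingest) -> ridge phases
    -> DBI with inter-subject surrogate thresholds -> DTF -> group
    comparison tables -> manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    root_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(
            ("simulate", "dbi_surrogates", "dtf"), root_seq.spawn(3)
        )
    }
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    # --- stage 1: recordings -------------------------------------------------
    logger.info("stage simulate/ingest")
    if config.input_dir:
        recs = [read_recording(p) for p in sorted(Path(config.input_dir).glob("*.csv"))]
    else:
        sim_seq = np.random.SeedSequence(stage_seeds["simulate"]).spawn(2)
        recs = simulate_cohort(
            config.n_subjects_control, "control",
            int(sim_seq[0].generate_state(1)[0] % (2**31 - 1)),
            coupling=config.coupling_control,
            duration=config.duration, sampling_rate=config.sampling_rate,
        ) + simulate_cohort(
            config.n_subjects_t1d, "t1d",
            int(sim_seq[1].generate_state(1)[0] % (2**31 - 1)),
            coupling=config.coupling_t1d,
            duration=config.duration, sampling_rate=config.sampling_rate,
        )
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for r in recs:
            write_recording(r, rec_dir / f"{r.subject_id}.csv")
    if not recs:
        raise RuntimeError("stage simulate/ingest produced no recordings")
    manifest["stages"]["recordings"] = {"n_subjects": len(recs)}

    # --- stage 2: ridge phases ----------------------------------------------
    logger.info("stage preprocess (%d subjects)", len(recs))
    ridge_dir = out / "ridges"
    ridge_dir.mkdir(exist_ok=True)
    phases: dict[str, dict[str, RidgeCurve]] = {}
    groups: dict[str, str] = {}
    for rec in recs:
        try:
            phases[rec.subject_id] = _subject_phases(rec, config)
        except Exception as err:
            raise RuntimeError(
                f"stage preprocess failed for subject {rec.subject_id}: {err}"
            ) from err
        groups[rec.subject_id] = rec.group
        for key, ridge in phases[rec.subject_id].items():
            pd.DataFrame(
                {
                    "time_s": ridge.times,
                    "frequency_hz": ridge.frequency,
                    "amplitude": ridge.amplitude,
                    "phase_rad": ridge.phase,
                }
            ).to_csv(ridge_dir / f"{rec.subject_id}_{key}.csv", index=False, float_format="%.8g")
    manifest["stages"]["ridges"] = {"n_files": len(recs) * 3}

    # --- stage 3: DBI --------------------------------------------------------
    logger.info("stage dbi")
    thresholds = dbi_surrogate_thresholds(phases, config, stage_seeds["dbi_surrogates"])
    (out / "dbi_thresholds.json").write_text(
        json.dumps(
            {
                name: {
                    "median_1to2": th.median_1to2,
                    "median_2to1": th.median_2to1,
                    "n_surrogates": th.n_surrogates,
                    "n_windows_total": th.n_windows_total,
                }
                for name, th in thresholds.items()
            },
            indent=2,
        )
    )
    dbi_dir = out / "dbi"
    dbi_dir.mkdir(exist_ok=True)
    dbi_results: dict[str, dict[str, list[dbi_mod.CouplingWindowResult]]] = {}
    dbi_rows = 0
    for subject, ph in phases.items():
        by_pair = {}
        for name, k1, k2 in DBI_PAIRS:
            res = _run_dbi_pair(ph, k1, k2, config)
            res = dbi_mod.apply_surrogate_threshold(res, thresholds[name])
            by_pair[name] = res
            pd.DataFrame(
                [
                    {
                        "window_index": w.window_index,
                        "start_s": w.window_start,
                        "s_1to2": w.s_1to2,
                        "s_2to1": w.s_2to1,
                        "d": np.nan if w.d is None else w.d,
                        "significant_1to2": w.significant_1to2,
                        "significant_2to1": w.significant_2to1,
                    }
                    for w in res
                ]
            ).to_csv(dbi_dir / f"{subject}_{name}.csv", index=False, float_format="%.8g")
            dbi_rows += len(res)
        dbi_results[subject] = by_pair
    manifest["stages"]["dbi"] = {
        "windows_per_pair": len(next(iter(dbi_results.values()))[DBI_PAIRS[0][0]]),
        "total_rows": dbi_rows,
    }

    # --- stage 4: DTF --------------------------------------------------------
    logger.info("stage dtf")
    dtf_dir = out / "dtf"
    dtf_dir.mkdir(exist_ok=True)
    dtf_seq = np.random.SeedSequence(stage_seeds["dtf"]).spawn(len(recs))
    dtf_results: dict[str, list[dtf_mod.DTFResult]] = {}
    dtf_rows = 0
    for rec, sseq in zip(recs, dtf_seq):
        res = dtf_mod.run_dtf(
            rec,
            window=config.dtf_window,
            order=config.dtf_order,
            band=config.dtf_band,
            alpha=config.dtf_alpha,
            n_null=config.dtf_n_null,
            seed=int(sseq.generate_state(1)[0] % (2**31 - 1)),
        )
        dtf_results[rec.subject_id] = res
        rows = []
        names = rec.channel_names
        for w in res:
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    rows.append(
                        {
                            "window_index": w.window_index,
                            "source": names[j],
                            "sink": names[i],
                            "ss_band_mean": w.ss_band_mean[i, j],
                            "n_significant_bins": int(
                                w.significance_mask[
                                    (w.frequencies > config.dtf_band[0])
                                    & (w.frequencies <= config.dtf_band[1]),
                                    i,
                                    j,
                                ].sum()
                            ),
                        }
                    )
        pd.DataFrame(rows).to_csv(
            dtf_dir / f"{rec.subject_id}.csv", index=False, float_format="%.8g"
        )
        dtf_rows += len(rows)
    manifest["stages"]["dtf"] = {
        "windows_per_subject": len(next(iter(dtf_results.values()))),
        "total_rows": dtf_rows,
    }

    # --- stage 5: group comparison ------------------------------------------
    logger.info("stage compare")
    control_ids = [s for s, g in groups.items() if g == "control"]
    t1d_ids = [s for s, g in groups.items() if g == "t1d"]
    tables = {}
    if control_ids and t1d_ids:
        dbi_meas = collect_dbi_measures(dbi_results)
        dtf_meas = collect_dtf_measures(dtf_results)
        for method, meas in (("dbi", dbi_meas), ("dtf", dtf_meas)):
            ctl = {m: {s: v for s, v in by.items() if s in control_ids} for m, by in meas.items()}
            pat = {m: {s: v for s, v in by.items() if s in t1d_ids} for m, by in meas.items()}
            rows = stats_mod.build_comparison_table(
                ctl, pat, method=method, level=config.comparison_level
            )
            df = pd.DataFrame(
                [
                    {
                        "interaction": r.interaction,
                        "measure": r.measure,
                        "median_control": r.median_control,
                        "median_t1d": r.median_t1d,
                        "p_H1a": r.p_h1a,
                        "p_H1b": r.p_h1b,
                        "n_control": r.n_control,
                        "n_t1d": r.n_t1d,
                    }
                    for r in rows
                ]
            )
            df.to_csv(out / f"comparison_{method}.csv", index=False, float_format="%.8g")
            tables[method] = rows
    manifest["stages"]["compare"] = {"methods": sorted(tables)}

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
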