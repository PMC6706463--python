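"""End-to-end orchestration: simulate/load -> PLI -> metrics -> statistics.

Seeds are derived hierarchically from the master seed (master ->
per-subject -> per-(subject, sparsity) streams), so any stage can be
re-run in isolation and reproduce its outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import instantaneous_phase, mean_global_pli, pli_matrix
from .metrics import DEFAULT_SPARSITY_GRID, sparsity_sweep
from .montage import Montage, default_montage
from .preprocessing import Recording, bandpass, isolate_band, reject_epochs, segment
from .stats import (
    anova_oneway,
    default_rois,
    define_rois,
    electrodewise_anova,
    posthoc_bonferroni,
    roi_summary,
)
from .synthetic import SyntheticCohortSpec, simulate_cohort, write_cohort

log = logging.getLogger("plinet")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Defaults reproduce the reference analysis settings: 3-s epochs, 50
    per subject, 75 ms trim, alpha band 8-13 Hz after a 0.1-45 Hz
    pre-filter, sparsity grid 0.05..0.50 step 0.05, 100 random networks.
    """

    input_dir: str | None = None  # cohort on disk; None -> simulate
    output_dir: str = "plinet_run"
    simulation: dict = field(default_factory=dict)  # SyntheticCohortSpec overrides
    band: tuple = (8.0, 13.0)
    prefilter: tuple | None = (0.1, 45.0)
    epoch_length: float = 3.0
    n_epochs: int = 50
    trim: float = 0.075
    amplitude_limit: float | None = None
    sparsity_grid: tuple = DEFAULT_SPARSITY_GRID
    n_random: int = 100
    include_sigma: bool = True
    include_global: bool = True
    scales: tuple = ("MCCB", "GAF")
    roi_alpha: float = 0.001
    use_default_rois: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("band", "prefilter", "sparsity_grid", "scales"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("band", "prefilter", "sparsity_grid", "scales"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _load_cohort(input_dir: Path):
    table = pd.read_csv(input_dir / "cohort.csv")
    recordings = []
    for sid in table["subject_id"]:
        stem = input_dir / str(sid)
        if stem.with_suffix(".npy").exists():
            recordings.append(Recording.from_container(stem))
        elif (input_dir / f"{sid}.edf").exists():
            recordings.append(Recording.from_edf(input_dir / f"{sid}.edf"))
        else:
            raise FileNotFoundError(
                f"no recording found for cohort subject {sid!r} in {input_dir}"
            )
    montage_path = input_dir / "montage.csv"
    montage = Montage.from_csv(montage_path) if montage_path.exists() else None
    return recordings, table, montage


def validate_inputs(config: PipelineConfig) -> list:
    """Consistency checks on an on-disk cohort; returns all problems found."""
    problems = []
    if config.input_dir is None:
        return problems
    input_dir = Path(config.input_dir)
    if not (input_dir / "cohort.csv").exists():
        return [f"missing cohort table {input_dir / 'cohort.csv'}"]
    table = pd.read_csv(input_dir / "cohort.csv")
    if "subject_id" not in table.columns or "group" not in table.columns:
        problems.append("cohort.csv must have subject_id and group columns")
        return problems
    montage = None
    if (input_dir / "montage.csv").exists():
        try:
            montage = Montage.from_csv(input_dir / "montage.csv")
        except ValueError as exc:
            problems.append(f"montage: {exc}")
    n_channels = None
    rates = set()
    for sid in table["subject_id"]:
        stem = input_dir / str(sid)
        if not (stem.with_suffix(".npy").exists()
                or (input_dir / f"{sid}.edf").exists()):
            problems.append(f"cohort row {sid!r} has no recording file")
            continue
        try:
            rec = (Recording.from_container(stem)
                   if stem.with_suffix(".npy").exists()
                   else Recording.from_edf(input_dir / f"{sid}.edf"))
        except Exception as exc:  # unreadable file is itself the finding
            problems.append(f"recording {sid!r} unreadable: {exc}")
            continue
        rates.add(rec.sampling_rate)
        if n_channels is None:
            n_channels = rec.n_channels
        elif rec.n_channels != n_channels:
            problems.append(
                f"recording {sid!r} has {rec.n_channels} channels, "
                f"others have {n_channels}"
            )
        need = int(round(config.epoch_length * rec.sampling_rate)) * config.n_epochs
        if rec.n_samples < need:
            problems.append(
                f"recording {sid!r} too short for {config.n_epochs} epochs "
                f"of {config.epoch_length} s"
            )
    if len(rates) > 1:
        problems.append(f"mixed sampling rates across recordings: {sorted(rates)}")
    if montage is not None and n_channels is not None:
        if montage.n_electrodes != n_channels:
            problems.append(
                f"montage covers {montage.n_electrodes} electrodes, "
                f"recordings have {n_channels} channels"
            )
    return problems


def analyze_subject(recording: Recording, config: PipelineConfig, seed: int):
    """One subject through preprocessing, PLI and the sparsity sweep."""
    rec = recording
    if config.prefilter is not None:
        rec = bandpass(rec, *config.prefilter)
    epochs = segment(rec, config.epoch_length, config.n_epochs)
    epochs = isolate_band(epochs, *config.band, trim=config.trim)
    if config.amplitude_limit is not None:
        epochs, _ = reject_epochs(epochs, config.amplitude_limit)
    phases = instantaneous_phase(epochs)
    matrix = pli_matrix(phases)
    profile = sparsity_sweep(
        matrix,
        grid=config.sparsity_grid,
        n_random=config.n_random,
        seed=seed,
        include_sigma=config.include_sigma,
        include_global=config.include_global,
    )
    return matrix, profile


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the populated run directory.

    Outputs per subject: the PLI adjacency (binary container + text) and
    the metric/AUC table (CSV). Per cohort: group statistics on global
    PLI and mean degree AUC, the electrode-wise ANOVA map, ROI report
    and correlation report (JSON/CSV), plus a machine-readable manifest
    of config, seeds and software version. Identical config + seed give
    identical outputs.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "stages": [],
        "status": "running",
    }

    def _fail(stage, subject, exc):
        manifest["status"] = "failed"
        manifest["failure"] = {
            "stage": stage,
            "subject": subject,
            "error": str(exc),
        }
        _write_manifest(out, manifest)
        raise RuntimeError(
            f"pipeline stage {stage!r} failed for subject {subject!r}: {exc}"
        ) from exc

    t0 = time.time()
    if config.input_dir is None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        spec = SyntheticCohortSpec(**sim_kwargs)
        recordings, table = simulate_cohort(spec)
        montage = default_montage(spec.n_channels)
        write_cohort(out / "cohort", recordings, table, montage)
        log.info("simulated %d subjects in %.1f s", len(recordings),
                 time.time() - t0)
    else:
        problems = validate_inputs(config)
        if problems:
            _fail("validate", None, ValueError("; ".join(problems)))
        recordings, table, montage = _load_cohort(Path(config.input_dir))
        if montage is None:
            montage = default_montage(recordings[0].n_channels)
    manifest["stages"].append({"stage": "inputs", "seconds": time.time() - t0})

    profiles = {}
    pli_means = {}
    subj_dir = out / "subjects"
    subj_dir.mkdir(exist_ok=True)
    master = np.random.SeedSequence(entropy=config.seed)
    for si, rec in enumerate(recordings):
        ts = time.time()
        subject_seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
        try:
            matrix, profile = analyze_subject(rec, config, seed=subject_seed)
        except Exception as exc:
            _fail("analyze", rec.subject_id, exc)
        matrix.to_container(subj_dir / f"{rec.subject_id}_pli")
        matrix.to_text(subj_dir / f"{rec.subject_id}_pli.tsv")
        from .metrics import profile_to_frame

        profile_to_frame(profile).to_csv(
            subj_dir / f"{rec.subject_id}_metrics.csv", index=False
        )
        pd.DataFrame(
            {"electrode": list(matrix.channel_labels),
             "degree_auc": profile.degree_auc}
        ).to_csv(subj_dir / f"{rec.subject_id}_degree_auc.csv", index=False)
        profiles[rec.subject_id] = profile
        pli_means[rec.subject_id] = mean_global_pli(matrix)
        log.info("subject %s done in %.1f s", rec.subject_id, time.time() - ts)

    ts = time.time()
    try:
        report = _cohort_statistics(profiles, pli_means, table, montage, config)
    except Exception as exc:
        _fail("statistics", None, exc)
    with open(out / "group_statistics.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["stages"].append({"stage": "statistics", "seconds": time.time() - ts})
    manifest["status"] = "complete"
    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _cohort_statistics(profiles, pli_means, table, montage, config) -> dict:
    by_group_pli: dict = {}
    by_group_deg: dict = {}
    group_of = dict(zip(table["subject_id"], table["group"]))
    for sid, prof in profiles.items():
        g = group_of[sid]
        by_group_pli.setdefault(g, []).append(pli_means[sid])
        by_group_deg.setdefault(g, []).append(float(np.mean(prof.degree_auc)))

    pli_res = anova_oneway(by_group_pli)
    deg_res = anova_oneway(by_group_deg)
    report = {
        "global_pli": {
            "group_means": {g: float(np.mean(v)) for g, v in by_group_pli.items()},
            "anova": pli_res.as_dict(),
            "posthoc": {f"{a}|{b}": p
                        for (a, b), p in posthoc_bonferroni(by_group_pli).items()},
        },
        "mean_degree_auc": {
            "group_means": {g: float(np.mean(v)) for g, v in by_group_deg.items()},
            "anova": deg_res.as_dict(),
            "posthoc": {f"{a}|{b}": p
                        for (a, b), p in posthoc_bonferroni(by_group_deg).items()},
        },
    }

    maps: dict = {}
    for sid, prof in profiles.items():
        maps.setdefault(group_of[sid], []).append(prof.degree_auc)
    maps = {g: np.vstack(v) for g, v in maps.items()}
    emap = electrodewise_anova(maps)
    report["electrodewise_anova"] = {
        "n_electrodes": int(len(emap)),
        "min_p": float(np.nanmin(emap["p"])),
        "n_significant": int((emap["p"] < config.roi_alpha).sum()),
    }

    if config.use_default_rois:
        roiset = default_rois()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            roiset = define_rois(emap["p"].to_numpy(), montage,
                                 alpha=config.roi_alpha)
    if len(roiset):
        rs = roi_summary(profiles, roiset, table, scales=config.scales)
        report["roi"] = {
            "electrodes": {name: list(ids) for name, ids in roiset},
            "anova": {name: res.as_dict() for name, res in rs["anova"].items()},
            "correlations": {
                f"{name}|{scale}": c.as_dict()
                for (name, scale), c in rs["correlations"].items()
            },
        }
    else:
        report["roi"] = {"electrodes": {}, "note": "no electrode passed the threshold"}

    scales = [s for s in config.scales if s in table.columns]
    pooled = {}
    deg_by_sid = {sid: float(np.mean(p.degree_auc)) for sid, p in profiles.items()}
    for scale in scales:
        sids = [s for s in deg_by_sid if np.isfinite(
            table.set_index("subject_id").loc[s, scale])]
        x = np.array([deg_by_sid[s] for s in sids])
        y = table.set_index("subject_id").loc[sids, scale].to_numpy(float)
        from .stats import pearson_correlation

        c = pearson_correlation(x, y, pair=("mean degree AUC", scale),
                                n_tests=len(scales))
        pooled[scale] = c.as_dict()
    report["global_degree_correlations"] = pooled
    return report
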