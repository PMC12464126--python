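"""End-to-end orchestration: simulate -> cluster -> backfit -> metrics -> stats.

Each stage reads the previous stage's persisted artifacts (EDF recordings,
TSV map/segmentation/metrics tables) and writes its own, so any stage can
be re-run independently and downstream outputs are exactly reproducible
from intermediates.  :func:`run_study` chains all stages inside one run
directory and returns the result bundle in memory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backfit import (UNASSIGNED, Segmentation, apply_segment_threshold,
                      fit_labels, reject_short, smooth_labels,
                      temporal_metrics)
from .bands import CANONICAL_BANDS
from .clustering import (MicrostateModel, canonical_templates, compute_gfp,
                         group_cluster, individual_topographies, label_maps)
from .preprocessing import average_reference, bandpass, downsample, notch_filter
from .recording import Recording, load_standard_montage, read_edf, write_edf
from .stats import run_statistics
from .synthetic import PlantedEffect, StudyDesign, make_study, make_template_maps

__all__ = ["RunConfig", "run_study", "stage_simulate", "stage_cluster",
           "stage_backfit", "stage_metrics", "stage_stats"]


@dataclass
class RunConfig:
    """Parameters of one full study run.

    Back-fitting defaults are the standard printed parameter set: 0.7
    correlation threshold, smoothing half-window 3 frames, Besag factor 10,
    and rejection of segments shorter than 3 frames.
    """

    seed: int = 0
    out_dir: str = "results/run"
    synthetic: dict = field(default_factory=dict)
    bands: tuple[str, ...] = ("broadband",)
    n_individual_maps: int = 7
    k_range: tuple[int, int] = (2, 8)
    n_init: int = 10
    notch_hz: float | None = None
    target_fs: float | None = None
    threshold: float = 0.7
    threshold_mode: str = "segment"
    half_window: int = 3
    besag: float = 10.0
    min_frames: int = 3
    q: float = 0.05
    coupling_cells: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.bands = tuple(cfg.bands)
        cfg.k_range = tuple(cfg.k_range)
        return cfg

    def to_design(self) -> StudyDesign:
        spec = dict(self.synthetic)
        effects = tuple(
            PlantedEffect(
                condition=e["condition"],
                sessions=tuple(e["sessions"]),
                band=e["band"],
                state=int(e["state"]),
                parameter=e["parameter"],
                shift=float(e["shift"]),
            )
            for e in spec.pop("planted_effects", [])
        )
        for key in ("conditions", "sessions", "bands"):
            if key in spec:
                spec[key] = tuple(spec[key])
        return StudyDesign(planted_effects=effects, seed=self.seed, **spec)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _rec_seed(base: int, *parts) -> int:
    h = hashlib.sha256(("/".join(map(str, (base,) + parts))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _rec_stem(rec: Recording) -> str:
    return f"{rec.subject}_{rec.condition}_{rec.session}"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# stages

def stage_simulate(config: RunConfig, run_dir: Path) -> tuple[list[Recording], pd.DataFrame]:
    """Generate the synthetic study; write EDF recordings and the truth table."""
    design = config.to_design()
    maps = make_template_maps(design.n_states, 64, seed=config.seed)
    recordings, truth = make_study(design, maps)
    rec_dir = run_dir / "recordings"
    rec_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for rec in recordings:
        path = rec_dir / f"{_rec_stem(rec)}.edf"
        write_edf(rec, path)
        index_rows.append((rec.subject, rec.condition, rec.session, path.name))
    _write_tsv(pd.DataFrame(index_rows,
                            columns=["subject", "condition", "session", "file"]),
               run_dir / "recordings_index.tsv")
    _write_tsv(truth, run_dir / "ground_truth.tsv")
    np.savetxt(run_dir / "template_maps.tsv", maps.maps, delimiter="\t")
    return recordings, truth


def _load_recordings(run_dir: Path) -> list[Recording]:
    index = pd.read_csv(run_dir / "recordings_index.tsv", sep="\t")
    recs = []
    for row in index.itertuples():
        rec = read_edf(run_dir / "recordings" / row.file,
                       subject=row.subject, condition=row.condition,
                       session=row.session)
        try:
            names, pos = load_standard_montage(rec.n_channels)
            if names == rec.ch_names:
                rec.positions = pos
        except ValueError:
            pass
        recs.append(rec)
    return recs


def _preprocess(rec: Recording, config: RunConfig, band: str) -> Recording:
    out = rec
    if config.notch_hz is not None:
        out = notch_filter(out, config.notch_hz)
    out = bandpass(out, CANONICAL_BANDS[band])
    if config.target_fs is not None and config.target_fs < out.fs:
        out = downsample(out, config.target_fs)
    return average_reference(out)


def stage_cluster(config: RunConfig, run_dir: Path,
                  recordings: list[Recording] | None = None) -> dict[str, MicrostateModel]:
    """Two-level clustering per band; writes group maps and model metadata."""
    recs = recordings if recordings is not None else _load_recordings(run_dir)
    models: dict[str, MicrostateModel] = {}
    for band in config.bands:
        pooled = []
        for i, rec in enumerate(recs):
            filtered = _preprocess(rec, config, band)
            pooled.append(individual_topographies(
                filtered, n_maps=config.n_individual_maps,
                n_init=config.n_init,
                seed=_rec_seed(config.seed, band, _rec_stem(rec))))
        pooled = np.vstack(pooled)
        lo, hi = min(config.k_range), max(config.k_range)
        model = group_cluster(pooled, range(lo, hi + 1),
                              seed=_rec_seed(config.seed, band, "group"),
                              n_init=config.n_init, band=band)
        if recs[0].positions is not None and model.K <= 7:
            ref_maps, ref_names = canonical_templates(recs[0].positions)
            model = label_maps(model, ref_maps, ref_names)
        models[band] = model
        df = pd.DataFrame(model.maps, columns=recs[0].ch_names)
        df.insert(0, "state", model.labels or list(range(model.K)))
        _write_tsv(df, run_dir / f"maps_{band}.tsv")
        meta = {"band": band, "K": model.K, "gev": model.gev,
                "labels": model.labels,
                "cluster_gev": (model.cluster_gev.tolist()
                                if model.cluster_gev is not None else None)}
        (run_dir / f"model_{band}.json").write_text(json.dumps(meta, indent=2))
    return models


def _load_models(config: RunConfig, run_dir: Path) -> dict[str, MicrostateModel]:
    models = {}
    for band in config.bands:
        df = pd.read_csv(run_dir / f"maps_{band}.tsv", sep="\t")
        meta = json.loads((run_dir / f"model_{band}.json").read_text())
        models[band] = MicrostateModel(
            maps=df.drop(columns=["state"]).to_numpy(),
            gev=meta["gev"],
            labels=meta["labels"],
            band=band,
        )
    return models


def stage_backfit(config: RunConfig, run_dir: Path,
                  recordings: list[Recording] | None = None,
                  models: dict[str, MicrostateModel] | None = None,
                  ) -> dict[tuple, Segmentation]:
    """Fit, smooth and clean per-sample labels; writes segmentation TSVs."""
    recs = recordings if recordings is not None else _load_recordings(run_dir)
    models = models if models is not None else _load_models(config, run_dir)
    seg_dir = run_dir / "segmentations"
    seg_dir.mkdir(parents=True, exist_ok=True)
    segs: dict[tuple, Segmentation] = {}
    for band, model in models.items():
        for rec in recs:
            filtered = _preprocess(rec, config, band)
            gfp = compute_gfp(filtered).values
            if config.threshold_mode == "sample":
                # per-sample threshold before smoothing
                seg = fit_labels(filtered, model, threshold=config.threshold)
                seg = smooth_labels(seg, gfp, half_window=config.half_window,
                                    besag=config.besag)
                seg = reject_short(seg, min_frames=config.min_frames)
            else:
                # assign everywhere, smooth, then exclude poorly fitting
                # segments as a whole (narrow-band carriers pass through
                # zero twice a cycle; a per-sample threshold would cut
                # every segment at those moments)
                seg = fit_labels(filtered, model, threshold=0.0)
                seg = smooth_labels(seg, gfp, half_window=config.half_window,
                                    besag=config.besag)
                seg = reject_short(seg, min_frames=config.min_frames)
                seg = apply_segment_threshold(seg, gfp, config.threshold)
            segs[(band, rec.subject, rec.condition, rec.session)] = seg
            _write_tsv(pd.DataFrame({"sample": np.arange(seg.n_samples),
                                     "label": seg.labels}),
                       seg_dir / f"{band}_{_rec_stem(rec)}.tsv")
    return segs


def stage_metrics(config: RunConfig, run_dir: Path,
                  segs: dict[tuple, Segmentation] | None = None,
                  models: dict[str, MicrostateModel] | None = None) -> pd.DataFrame:
    """Temporal metrics per recording and state; writes the long metrics table."""
    models = models if models is not None else _load_models(config, run_dir)
    if segs is None:
        segs = {}
        seg_dir = run_dir / "segmentations"
        index = pd.read_csv(run_dir / "recordings_index.tsv", sep="\t")
        fs = None
        for band in config.bands:
            for row in index.itertuples():
                df = pd.read_csv(
                    seg_dir / f"{band}_{row.subject}_{row.condition}_{row.session}.tsv",
                    sep="\t")
                if fs is None:
                    with open(run_dir / "provenance.json") as fh:
                        fs = json.load(fh)["analysis_fs"]
                segs[(band, row.subject, row.condition, row.session)] = \
                    Segmentation(labels=df["label"].to_numpy(), fs=fs,
                                 state_names=models[band].labels)
    rows = []
    for (band, subj, cond, sess), seg in segs.items():
        table = temporal_metrics(seg, n_states=models[band].K)
        table["subject"], table["condition"] = subj, cond
        table["session"], table["band"] = sess, band
        rows.append(table)
    metrics = pd.concat(rows, ignore_index=True)
    names = metrics.pop("state_name")
    metrics["state"] = names.where(names.notna(), metrics["state"].astype(str))
    metrics = metrics[["subject", "condition", "session", "band", "state",
                       "mean_duration", "occurrence", "coverage"]]
    _write_tsv(metrics.sort_values(
        ["band", "condition", "subject", "session", "state"]).reset_index(drop=True),
        run_dir / "metrics.tsv")
    return metrics


def stage_stats(config: RunConfig, run_dir: Path,
                metrics: pd.DataFrame | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wilcoxon/FDR/effect-size battery plus coupling-corrected correlations."""
    if metrics is None:
        metrics = pd.read_csv(run_dir / "metrics.tsv", sep="\t")
    comparisons, coupling = run_statistics(
        metrics, q=config.q, coupling_cells=config.coupling_cells or None)
    _write_tsv(comparisons, run_dir / "comparisons.tsv")
    _write_tsv(coupling, run_dir / "coupling.tsv")
    return comparisons, coupling


def run_study(config: RunConfig) -> dict:
    """Run every stage in order inside ``config.out_dir``; return the bundle."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    recordings, truth = stage_simulate(config, run_dir)
    provenance = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "bandstates_version": __version__,
        "numpy_version": np.__version__,
        "analysis_fs": float(config.target_fs or recordings[0].fs),
    }
    (run_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))
    models = stage_cluster(config, run_dir, recordings)
    segs = stage_backfit(config, run_dir, recordings, models)
    metrics = stage_metrics(config, run_dir, segs, models)
    comparisons, coupling = stage_stats(config, run_dir, metrics)
    return {
        "recordings": recordings,
        "truth": truth,
        "models": models,
        "segmentations": segs,
        "metrics": metrics,
        "comparisons": comparisons,
        "coupling": coupling,
        "run_dir": run_dir,
    }
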