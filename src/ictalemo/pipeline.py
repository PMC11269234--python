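"""End-to-end experiment orchestration.

The evolutionary-transfer protocol: features are extracted for the whole
collection, the collection is stratified into an outer train/test
partition, NSGA-II selects a feature mask using cross-validation on the
training partition only, and the GRNN — trained on the training
partition with both the full 512-column mask and the selected mask — is
scored on the held-out partition. The held-out partition never
participates in feature scaling, sigma selection, or mask optimization.

All randomness flows from one master seed through named substreams
(synthesis, EA, CV, sigma search, outer split, solution selection), so a
report can be replayed bit-for-bit from its recorded seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ictalemo import evaluation, grnn
from ictalemo.emo_nsga2 import EAConfig, ParetoArchive, run_nsga2
from ictalemo.feature_extraction import EmbeddingParams, FeatureMatrix, build_feature_matrix
from ictalemo.signal_io import EEGSegment, Label, read_segments_csv, read_labels, resample_segment
from ictalemo.synthetic_eeg import SynthConfig, generate_dataset
from ictalemo import wpt_mra

logger = logging.getLogger(__name__)

# substream indices off the master seed
_SUB_SYNTH, _SUB_SPLIT, _SUB_CV, _SUB_EA, _SUB_SIGMA, _SUB_SELECT = range(6)


def _substream_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    """Everything needed to replay one experiment.

    Data comes either from the synthetic generator (``synth``) or from a
    CSV segment matrix plus a label sidecar (``data_csv``/``labels_file``).
    """

    synth: SynthConfig | None = None
    data_csv: str | None = None
    labels_file: str | None = None
    data_fs: float = 200.0
    orientation: str = "rows"
    resample_fs: float | None = None
    level: int = wpt_mra.DEFAULT_LEVEL
    wavelet: str = wpt_mra.DEFAULT_WAVELET
    boundary_mode: str = wpt_mra.DEFAULT_BOUNDARY
    tau: int = 1
    ea: EAConfig = field(default_factory=EAConfig)
    sigma_policy: str = "grid"  # grid-search on the training partition; "fixed" uses ea.sigma
    test_fraction: float = 0.3
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.synth is None and self.data_csv is None:
            raise ValueError("either a synthetic config or a data CSV must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        if "ea" in raw and raw["ea"] is not None:
            raw["ea"] = EAConfig(**raw["ea"])
        return cls(**raw)


def load_segments(cfg: ExperimentConfig) -> list[EEGSegment]:
    """Materialize the segment collection from the configured source."""
    if cfg.synth is not None:
        synth = SynthConfig(**{**asdict(cfg.synth), "seed": _substream_seed(cfg.seed, _SUB_SYNTH) if cfg.synth.seed == 0 else cfg.synth.seed})
        segments = generate_dataset(synth)
    else:
        labels = read_labels(cfg.labels_file) if cfg.labels_file else None
        segments = read_segments_csv(cfg.data_csv, fs=cfg.data_fs, orientation=cfg.orientation, labels=labels)
    if cfg.resample_fs is not None:
        segments = [resample_segment(s, cfg.resample_fs) for s in segments]
    return segments


def _stratified_outer_split(labels01: np.ndarray, test_fraction: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in (0, 1):
        members = np.where(labels01 == cls)[0]
        if len(members) < 2:
            raise ValueError("both classes need >= 2 segments for a stratified outer split")
        perm = rng.permutation(members)
        k = int(round(len(members) * test_fraction))
        k = min(max(k, 1), len(members) - 1)
        test_idx.append(perm[:k])
        train_idx.append(perm[k:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass
class ExperimentReport:
    """Held-out metrics for the full mask and the EMO-selected mask, plus replay info."""

    rows: list[dict]
    archive: ParetoArchive
    seeds: dict[str, int]
    timings: dict[str, float]

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.rows).to_csv(path, index=False)


def run_experiment(cfg: ExperimentConfig, feature_matrix: FeatureMatrix | None = None) -> ExperimentReport:
    """Run the full protocol and report held-out performance.

    ``feature_matrix`` may be supplied to skip synthesis/extraction (for
    pre-computed or deliberately modified matrices); rows must carry
    labels.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    if feature_matrix is None:
        segments = load_segments(cfg)
        params = EmbeddingParams(tau=cfg.tau)
        feature_matrix = build_feature_matrix(
            segments, level=cfg.level, wavelet_name=cfg.wavelet, boundary_mode=cfg.boundary_mode, params=params
        )
    timings["features_s"] = time.perf_counter() - t0
    labels01 = feature_matrix.labels01()

    seeds = {
        "master": cfg.seed,
        "outer_split": _substream_seed(cfg.seed, _SUB_SPLIT),
        "cv": _substream_seed(cfg.seed, _SUB_CV),
        "ea": _substream_seed(cfg.seed, _SUB_EA),
        "sigma": _substream_seed(cfg.seed, _SUB_SIGMA),
    }
    tr, te = _stratified_outer_split(labels01, cfg.test_fraction, np.random.default_rng(seeds["outer_split"]))
    if labels01[tr].min() == labels01[tr].max() or labels01[te].min() == labels01[te].max():
        raise ValueError("degenerate outer partition: a class is missing from train or test")

    train_fm = FeatureMatrix(
        values=feature_matrix.values[tr],
        columns=list(feature_matrix.columns),
        row_labels=[feature_matrix.row_labels[i] for i in tr],
    )

    if cfg.sigma_policy == "grid":
        sigma = grnn.grid_search_sigma(train_fm.values, labels01[tr], seed=seeds["sigma"])
    elif cfg.sigma_policy == "fixed":
        sigma = cfg.ea.sigma
    else:
        raise ValueError(f"unknown sigma policy {cfg.sigma_policy!r}")
    ea_cfg = EAConfig(**{**asdict(cfg.ea), "seed": seeds["ea"], "sigma": sigma})

    t1 = time.perf_counter()
    archive = run_nsga2(train_fm, ea_cfg, cv_seed=seeds["cv"])
    timings["nsga2_s"] = time.perf_counter() - t1
    assert archive.selected is not None

    full_mask = np.ones(feature_matrix.n_features, dtype=bool)
    rows = []
    for name, mask in (("full", full_mask), ("selected", archive.selected.mask)):
        o2 = evaluation.random_subsample_cv(
            train_fm, mask=mask, n_iter=ea_cfg.cv_iterations, sigma=sigma, seed=seeds["cv"]
        )
        rep = evaluation.holdout_report(
            feature_matrix.values[tr][:, mask], labels01[tr], feature_matrix.values[te][:, mask], labels01[te], sigma
        )
        rows.append({"mask_name": name, "O1": int(mask.sum()), "O2": o2, **rep.as_dict()})
    timings["total_s"] = time.perf_counter() - t0

    report = ExperimentReport(rows=rows, archive=archive, seeds=seeds, timings=timings)
    if cfg.output_dir is not None:
        _write_outputs(report, cfg)
    return report


def _write_outputs(report: ExperimentReport, cfg: ExperimentConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "results.csv")
    report.archive.front_to_csv(out / "pareto_front.csv")
    try:
        report.archive.plot_front(out / "pareto_front.png")
    except Exception:  # plotting is best-effort
        logger.exception("could not render Pareto plot")
    meta = {
        "seeds": report.seeds,
        "timings": report.timings,
        "ea": asdict(report.archive.config),
        "selected_o1": report.archive.selected.o1 if report.archive.selected else None,
        "selected_o2": report.archive.selected.o2 if report.archive.selected else None,
    }
    with open(out / "experiment.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    logger.info("wrote results to %s", out)
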