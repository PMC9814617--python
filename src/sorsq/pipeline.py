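"""End-to-end study workflow: simulate -> preprocess -> train -> screen.

`run_study_replication` composes the whole method: it generates the training
design (36 content-container combinations plus mixture/dilution augmentation)
and the 173-sample test cohort, preprocesses everything to scaled-subtracted
area-normalized spectra, fits the MCR comparison (traditional vs
scaled-subtracted variance attribution), trains PLS-4, PLS-8 and SVR models,
and scores fair/sub-potent/contaminated determinations for each model.

A run is reproducible from (config, seed): the global seed fans out to
per-stage seeds through a documented counter scheme (stage k uses
SeedSequence(seed).generate_state(k+1)[k] mod 2^31), and every artifact embeds
the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemometrics import SpectralMatrix, evaluate, fit_pls, fit_svr, mcr_als, match_components
from .preprocess import PreprocessConfig, baseline_whittaker, normalize_area, preprocess_pair
from .screening import ConfusionReport, Determination, ScreeningPolicy, determine, score
from .simulate import (
    CohortSpec,
    ContainerModel,
    DEFAULT_BANDS,
    DEFAULT_NOISE_SD,
    default_containers,
    generate_cohort,
    pure_component_spectrum,
)
from .spectra import ALCOHOLS, SpectralDataset, WavenumberGrid

logger = logging.getLogger("sorsq")

STAGE_TRAINING = 0
STAGE_TEST = 1


def stage_seed(seed: int, stage: int) -> int:
    """Per-stage seed: word ``stage`` of the SeedSequence stream, kept < 2^31."""
    return int(np.random.SeedSequence(seed).generate_state(stage + 1)[stage] % (2**31))


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 5
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    policy: ScreeningPolicy = field(default_factory=ScreeningPolicy)
    out_dir: Optional[str] = None
    log_level: str = "INFO"

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# preprocessing over datasets


def _container_windows(containers: Sequence[ContainerModel]) -> Dict[str, Tuple[float, ...]]:
    return {c.container_id: c.subtraction_windows for c in containers}


def preprocess_dataset(
    ds: SpectralDataset,
    containers: Optional[Sequence[ContainerModel]] = None,
    cfg: Optional[PreprocessConfig] = None,
) -> SpectralMatrix:
    """Scaled-subtracted, baseline-corrected, area-normalized spectra of a
    dataset as a SpectralMatrix (one row per sample)."""
    cfg = cfg or PreprocessConfig()
    windows = _container_windows(containers or default_containers())
    rows, ids = [], []
    for rec in ds.records:
        bands = windows.get(rec.container_id)
        content, _ = preprocess_pair(ds.pairs[rec.sample_id], cfg, container_bands=bands)
        rows.append(content.intensities)
        ids.append(rec.sample_id)
    return SpectralMatrix(X=np.array(rows), row_ids=ids, grid=ds.grid)


def traditional_matrix(ds: SpectralDataset, cfg: Optional[PreprocessConfig] = None) -> SpectralMatrix:
    """Traditional (zero-offset) spectra through Whittaker + area
    normalization only — the comparison dataset for the MCR exercise."""
    cfg = cfg or PreprocessConfig()
    rows, ids = [], []
    for rec in ds.records:
        s = baseline_whittaker(ds.pairs[rec.sample_id].traditional, cfg)
        if cfg.normalization == "area":
            s = normalize_area(s)
        rows.append(s.intensities)
        ids.append(rec.sample_id)
    return SpectralMatrix(X=np.array(rows), row_ids=ids, grid=ds.grid)


def combination_id(sample_id: str) -> str:
    """Replicates share a combination id: ``<combination>-r<k>`` -> ``<combination>``."""
    stem, sep, tail = sample_id.rpartition("-r")
    if sep and tail.isdigit():
        return stem
    return sample_id


def average_replicates(mat: SpectralMatrix, ds: SpectralDataset) -> Tuple[SpectralMatrix, np.ndarray, List[str]]:
    """Average replicate rows per combination; returns (matrix, Y, combo_ids)
    with Y the % v/v of the four alcohols per combination."""
    groups: Dict[str, List[int]] = {}
    for i, sid in enumerate(mat.row_ids):
        groups.setdefault(combination_id(sid), []).append(i)
    combo_ids = list(groups)
    X = np.array([mat.X[idx].mean(axis=0) for idx in groups.values()])
    Y = []
    for cid, idx in groups.items():
        rec = ds.record(mat.row_ids[idx[0]])
        if rec.formulation is None:
            raise ValueError(f"combination {cid!r} has unknown composition")
        Y.append(rec.formulation.alcohol_vector())
    return SpectralMatrix(X=X, row_ids=combo_ids, grid=mat.grid), np.array(Y), combo_ids


def response_matrix(ds: SpectralDataset, ids: Sequence[str]) -> np.ndarray:
    Y = []
    for sid in ids:
        rec = ds.record(sid)
        if rec.formulation is None:
            raise ValueError(f"sample {sid!r} has unknown composition")
        Y.append(rec.formulation.alcohol_vector())
    return np.array(Y)


# ---------------------------------------------------------------------------
# fingerprint feature selection for the kernel model


def fingerprint_mask(grid: WavenumberGrid, half_width: float = 45.0) -> np.ndarray:
    """Boolean mask of the wavenumber channels within ``half_width`` of any
    known component band (alcohols, glycerin, water).

    The kernel regression operates on these fingerprint windows only: the
    remaining channels carry no analyte signal, and excluding them keeps the
    noise of quiet spectral regions out of the RBF distances (which would
    otherwise bias predictions for low-transmittance containers toward the
    training mean).
    """
    nu = grid.values
    mask = np.zeros(nu.size, dtype=bool)
    for component, bands in DEFAULT_BANDS.items():
        for band in bands:
            mask |= np.abs(nu - band.center_ref) <= half_width
    return mask


@dataclass
class MaskedRegressor:
    """Regression model operating on a fixed wavenumber-channel subset."""

    mask: np.ndarray
    model: object

    @property
    def targets(self):
        return self.model.targets

    @property
    def cv_rmse(self):
        return self.model.cv_rmse

    @property
    def cv_r2(self):
        return self.model.cv_r2

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float)[:, self.mask])


# ---------------------------------------------------------------------------
# MCR comparison


def reference_spectra(
    grid: WavenumberGrid,
    containers: Optional[Sequence[ContainerModel]] = None,
) -> Dict[str, np.ndarray]:
    """Named reference spectra for component matching: the four alcohols at
    reference strength plus one surface spectrum per sharp-banded material."""
    refs: Dict[str, np.ndarray] = {}
    for a in ALCOHOLS:
        x_ref = 80.0 if a in ("ethanol", "methanol") else 75.0
        refs[a] = pure_component_spectrum(a, grid, x_ref).intensities
    seen = set()
    for c in containers or default_containers():
        if c.band_centers and c.material not in seen:
            seen.add(c.material)
            refs[f"container:{c.material}"] = c.surface_spectrum(grid)
    return refs


@dataclass
class McrComparison:
    traditional_fit: float
    traditional_container_share: float
    traditional_content_share: float
    subtracted_fit: float
    subtracted_container_share: float
    subtracted_content_share: float
    traditional_assignment: List[Tuple[str, float]]
    subtracted_assignment: List[Tuple[str, float]]


def mcr_comparison(
    trad: SpectralMatrix,
    sub: SpectralMatrix,
    k_traditional: int = 7,
    k_subtracted: int = 4,
    containers: Optional[Sequence[ContainerModel]] = None,
) -> McrComparison:
    """Variance attribution: MCR on traditional vs scaled-subtracted spectra.

    Components are assigned to alcohol or container references by maximal
    cosine similarity; the share of fitted variance carried by
    container-matched components quantifies how strongly surface signal
    dominates each representation.
    """
    refs = reference_spectra(trad.grid, containers)
    out = {}
    assignments = {}
    for name, mat, k in (("traditional", trad, k_traditional), ("subtracted", sub, k_subtracted)):
        model = mcr_als(mat, k=k)
        assign = match_components(model.S, refs)
        container_share = sum(
            fit for (ref_name, _), fit in zip(assign, model.per_component_fit)
            if ref_name.startswith("container:")
        )
        content_share = sum(
            fit for (ref_name, _), fit in zip(assign, model.per_component_fit)
            if ref_name and not ref_name.startswith("container:")
        )
        out[name] = (model.cumulative_fit, float(container_share), float(content_share))
        assignments[name] = assign
    return McrComparison(
        traditional_fit=out["traditional"][0],
        traditional_container_share=out["traditional"][1],
        traditional_content_share=out["traditional"][2],
        subtracted_fit=out["subtracted"][0],
        subtracted_container_share=out["subtracted"][1],
        subtracted_content_share=out["subtracted"][2],
        traditional_assignment=assignments["traditional"],
        subtracted_assignment=assignments["subtracted"],
    )


# ---------------------------------------------------------------------------
# full study replication


@dataclass
class StudyReport:
    config: RunConfig
    config_hash: str
    mcr: McrComparison
    regression: Dict[str, Dict[str, Dict[str, Dict[str, float]]]]  # method -> split -> alcohol -> metric
    confusions: Dict[str, ConfusionReport]
    determinations: Dict[str, List[Determination]]
    predictions: Dict[str, np.ndarray]
    truth_labels: List[str]
    test_ids: List[str]
    y_test: np.ndarray
    timings: Dict[str, float]

    def summary_dict(self) -> Dict:
        return {
            "config": self.config.to_dict(),
            "config_hash": self.config_hash,
            "mcr": {
                "traditional": {
                    "cumulative_fit": self.mcr.traditional_fit,
                    "container_share": self.mcr.traditional_container_share,
                    "content_share": self.mcr.traditional_content_share,
                },
                "scaled_subtracted": {
                    "cumulative_fit": self.mcr.subtracted_fit,
                    "container_share": self.mcr.subtracted_container_share,
                    "content_share": self.mcr.subtracted_content_share,
                },
            },
            "regression": self.regression,
            "screening": {
                m: {
                    "accuracy": rep.accuracy,
                    "matrix": rep.matrix.tolist(),
                    "labels": list(rep.labels),
                }
                for m, rep in self.confusions.items()
            },
            "timings": self.timings,
        }


def run_study_replication(cfg: Optional[RunConfig] = None) -> StudyReport:
    cfg = cfg or RunConfig()
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))
    containers = default_containers()
    timings: Dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    t0 = _stage("simulate")
    train_ds = generate_cohort(
        CohortSpec(seed=stage_seed(cfg.seed, STAGE_TRAINING), design="training",
                   noise_sd=cfg.noise_sd, n_replicates=cfg.n_replicates),
        containers,
    )
    test_ds = generate_cohort(
        CohortSpec(seed=stage_seed(cfg.seed, STAGE_TEST), design="study_test",
                   noise_sd=cfg.noise_sd),
        containers,
    )
    timings["simulate"] = time.perf_counter() - t0

    t0 = _stage("preprocess")
    train_sub = preprocess_dataset(train_ds, containers, cfg.preprocess)
    test_sub = preprocess_dataset(test_ds, containers, cfg.preprocess)
    timings["preprocess"] = time.perf_counter() - t0

    # MCR comparison on the 36 content-container combinations (replicate level)
    t0 = _stage("mcr")
    combo_ids = [r.sample_id for r in train_ds.records if r.sample_id.startswith("train-")]
    combo_ds = train_ds.subset(combo_ids)
    trad_mat = traditional_matrix(combo_ds, cfg.preprocess)
    keep = [i for i, sid in enumerate(train_sub.row_ids) if sid in set(combo_ids)]
    sub_mat = SpectralMatrix(X=train_sub.X[keep], row_ids=[train_sub.row_ids[i] for i in keep],
                             grid=train_sub.grid)
    mcr = mcr_comparison(trad_mat, sub_mat, containers=containers)
    timings["mcr"] = time.perf_counter() - t0

    # regression models on the replicate-averaged 78-spectrum training set
    t0 = _stage("train")
    train_mat, y_train, _ = average_replicates(train_sub, train_ds)
    y_test = response_matrix(test_ds, test_sub.row_ids)
    mask = fingerprint_mask(train_mat.grid)
    models = {
        "pls4": fit_pls(train_mat, y_train, n_lv=4),
        "pls8": fit_pls(train_mat, y_train, n_lv=8),
        "svr": MaskedRegressor(mask=mask, model=fit_svr(train_mat.X[:, mask], y_train)),
    }
    timings["train"] = time.perf_counter() - t0

    t0 = _stage("evaluate")
    regression: Dict[str, Dict] = {}
    predictions: Dict[str, np.ndarray] = {}
    for name, model in models.items():
        pred_report = evaluate(model, test_sub.X, y_test, split="prediction")
        cv = {
            a: {"rmse": float(model.cv_rmse[i]), "r2": float(model.cv_r2[i])}
            for i, a in enumerate(ALCOHOLS)
        }
        regression[name] = {"cross_validation": cv, "prediction": pred_report.as_dict()}
        predictions[name] = model.predict(test_sub.X)
    timings["evaluate"] = time.perf_counter() - t0

    t0 = _stage("screen")
    truth = [test_ds.record(sid).true_label or "fair" for sid in test_sub.row_ids]
    confusions: Dict[str, ConfusionReport] = {}
    dets: Dict[str, List[Determination]] = {}
    for name, pred in predictions.items():
        d = [
            determine(dict(zip(ALCOHOLS, row)), cfg.policy, sample_id=sid)
            for sid, row in zip(test_sub.row_ids, pred)
        ]
        dets[name] = d
        confusions[name] = score(d, truth)
    timings["screen"] = time.perf_counter() - t0

    report = StudyReport(
        config=cfg, config_hash=cfg.config_hash, mcr=mcr, regression=regression,
        confusions=confusions, determinations=dets, predictions=predictions,
        truth_labels=truth, test_ids=list(test_sub.row_ids), y_test=y_test,
        timings=timings,
    )
    if cfg.out_dir:
        write_report(report, Path(cfg.out_dir))
    return report


def write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = report.config_hash
    with open(out_dir / f"report-{tag}.json", "w") as fh:
        json.dump(report.summary_dict(), fh, indent=2, sort_keys=True)
    # per-sample predictions + determinations per method
    import csv

    with open(out_dir / f"predictions-{tag}.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        header = ["sample_id", "true_label"]
        for m in report.predictions:
            header += [f"{m}_{a}" for a in ALCOHOLS] + [f"{m}_label"]
        w.writerow(header)
        for i, sid in enumerate(report.test_ids):
            row = [sid, report.truth_labels[i]]
            for m, pred in report.predictions.items():
                row += [f"{v:.4f}" for v in pred[i]] + [report.determinations[m][i].label]
            w.writerow(row)
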