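"""The resampling protocol around PLS-DA.

One run consists of P independent train/test divisions, each model-trained T
times, for P*T folds in total. At every fold the two classes are first
rebalanced by a fresh bootstrap draw (patients of the larger class sampled
down to the smaller class's patient count, a fixed number of spectra drawn
per retained patient), then split patient-wise so replicate spectra of one
subject never straddle train and test, then a PLS-DA model is fitted with
its LV count chosen by patient-grouped cross-validation, and finally train
and test performance plus VIP scores are recorded. Results are aggregated
as mean/min/max per metric plus the element-wise mean VIP profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import FoldMetrics, ROCResult, confusion, roc_curve
from .plsda import PLSConfig, classify, cv_rmse, fit_pls, predict_scores, select_n_lv, vip_scores
from .preprocess import PreprocessConfig, preprocess_dataset
from .synth import PeakSpec, SpectraDataset, Spectrum

__all__ = [
    "ProtocolConfig",
    "FoldResult",
    "ProtocolSummary",
    "balance_classes",
    "patient_split",
    "run_protocol",
    "aggregate",
    "vip_band_report",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "roc_auc")


@dataclass(frozen=True)
class ProtocolConfig:
    """Resampling design: P divisions x T trainings, patient-wise 80/20
    split, bootstrap balancing with a fixed per-patient spectra draw.

    ``positive_label`` fixes the metric orientation; when None the class
    with fewer patients is treated as positive (the disease group of
    interest is the minority in both study designs).
    """

    P: int = 5
    T: int = 5
    train_fraction: float = 0.8
    spectra_per_patient_draw: int = 3
    balance_with_replacement: bool = False
    positive_label: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.P < 1 or self.T < 1:
            raise ValueError(f"P and T must be >= 1, got P={self.P}, T={self.T}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.spectra_per_patient_draw < 1:
            raise ValueError(f"spectra_per_patient_draw must be >= 1, got {self.spectra_per_patient_draw}")


@dataclass(eq=False)
class FoldResult:
    """Everything recorded for one (division p, training t) fold."""

    fold_id: tuple[int, int]
    n_lv_used: int
    train_metrics: FoldMetrics
    test_metrics: FoldMetrics
    train_roc: ROCResult
    test_roc: ROCResult
    vip: np.ndarray
    train_patient_ids: frozenset[str]
    test_patient_ids: frozenset[str]


@dataclass(eq=False)
class ProtocolSummary:
    """Mean/min/max per metric per set over all folds, plus the mean VIP
    profile; the twin of a classification-results summary table."""

    stats: dict[str, dict[str, tuple[float, float, float]]]  # set -> metric -> (mean, min, max)
    mean_vip: np.ndarray
    n_folds: int
    positive_label: str
    wavenumbers: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Wide table: one row per set, mean/min/max columns per metric."""
        rows = {}
        for set_name, metrics in self.stats.items():
            row = {}
            for m, (mean, mn, mx) in metrics.items():
                row[f"{m}_mean"], row[f"{m}_min"], row[f"{m}_max"] = mean, mn, mx
            rows[set_name] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("set")


def _draw_spectra(spectra: list[Spectrum], k: int, rng: np.random.Generator) -> list[Spectrum]:
    """k spectra from one patient: without replacement when possible."""
    if len(spectra) >= k:
        idx = rng.choice(len(spectra), size=k, replace=False)
    else:
        idx = rng.choice(len(spectra), size=k, replace=True)
    out = []
    for j, i in enumerate(sorted(int(v) for v in idx)):
        s = spectra[i]
        out.append(
            Spectrum(
                spectrum_id=f"{s.spectrum_id}#b{j + 1}",
                patient_id=s.patient_id,
                class_label=s.class_label,
                intensities=s.intensities,
            )
        )
    return out


def balance_classes(
    ds: SpectraDataset, cfg: ProtocolConfig, rng: np.random.Generator | None = None
) -> SpectraDataset:
    """Bootstrap balancing: equal patient counts, fixed spectra per patient.

    Patients of the larger class are sampled (without replacement by
    default) down to the smaller class's patient count; within every
    retained patient ``spectra_per_patient_draw`` spectra are drawn, without
    replacement when the patient has enough replicates and with replacement
    otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = ds.class_labels
    if len(labels) != 2:
        raise ValueError(f"balance_classes requires exactly 2 classes, got {labels}")
    pools = {lab: ds.patients_of_class(lab) for lab in labels}
    for lab, pats in pools.items():
        if not pats:
            raise ValueError(f"class {lab!r} has zero patients")
    n_keep = min(len(p) for p in pools.values())
    spectra: list[Spectrum] = []
    class_of_patient: dict[str, str] = {}
    for lab in labels:
        pats = pools[lab]
        if len(pats) > n_keep or cfg.balance_with_replacement:
            chosen = rng.choice(len(pats), size=n_keep, replace=cfg.balance_with_replacement)
            kept = [pats[int(i)] for i in sorted(set(chosen))] if not cfg.balance_with_replacement else [
                pats[int(i)] for i in chosen
            ]
        else:
            kept = list(pats)
        for dup, pid in enumerate(kept):
            # with-replacement draws can repeat a patient; keep ids unique
            out_pid = pid if kept.count(pid) == 1 else f"{pid}~r{dup + 1}"
            class_of_patient[out_pid] = lab
            drawn = _draw_spectra(ds.spectra_of_patient(pid), cfg.spectra_per_patient_draw, rng)
            for s in drawn:
                spectra.append(
                    Spectrum(
                        spectrum_id=f"{out_pid}/{s.spectrum_id}",
                        patient_id=out_pid,
                        class_label=lab,
                        intensities=s.intensities,
                    )
                )
    out = SpectraDataset(axis=ds.axis, spectra=spectra, class_of_patient=class_of_patient)
    out.validate()
    return out


def patient_split(
    ds: SpectraDataset, train_fraction: float, rng: np.random.Generator
) -> tuple[SpectraDataset, SpectraDataset]:
    """Whole-patient train/test split targeting a spectra-count fraction.

    One random patient per class is pinned to each side so both classes are
    represented in both sets; the remaining patients are shuffled and the
    prefix whose spectra count lands closest to train_fraction x total is
    assigned to train (ties toward the larger training set).
    """
    labels = ds.class_labels
    counts = {pid: len(ds.spectra_of_patient(pid)) for pid in ds.class_of_patient}
    for lab in labels:
        if len(ds.patients_of_class(lab)) < 2:
            raise ValueError(f"patient_split needs >= 2 patients per class, class {lab!r} has fewer")
    train_ids: set[str] = set()
    test_ids: set[str] = set()
    remaining: list[str] = []
    for lab in labels:
        pats = list(ds.patients_of_class(lab))
        rng.shuffle(pats)
        train_ids.add(pats[0])
        test_ids.add(pats[1])
        remaining.extend(pats[2:])
    rng.shuffle(remaining)
    total = sum(counts.values())
    target = train_fraction * total
    base = sum(counts[p] for p in train_ids)
    prefix_sums = np.cumsum([0] + [counts[p] for p in remaining]) + base
    gaps = np.abs(prefix_sums - target)
    best = int(np.flatnonzero(gaps == gaps.min())[-1])  # tie toward larger train set
    train_ids.update(remaining[:best])
    test_ids.update(remaining[best:])

    def subset(ids: set[str]) -> SpectraDataset:
        sub = SpectraDataset(
            axis=ds.axis,
            spectra=[s for s in ds.spectra if s.patient_id in ids],
            class_of_patient={p: c for p, c in ds.class_of_patient.items() if p in ids},
        )
        sub.validate()
        return sub

    return subset(train_ids), subset(test_ids)


def _positive_label(ds: SpectraDataset, cfg: ProtocolConfig) -> str:
    if cfg.positive_label is not None:
        if cfg.positive_label not in ds.class_labels:
            raise ValueError(f"positive_label {cfg.positive_label!r} not among classes {ds.class_labels}")
        return cfg.positive_label
    # default: the minority-patient class is the positive (disease) group
    return min(ds.class_labels, key=lambda lab: (len(ds.patients_of_class(lab)), lab))


def _evaluate(model, X, y_codes, threshold) -> tuple[FoldMetrics, ROCResult]:
    scores = predict_scores(model, X)
    return confusion(y_codes, classify(scores, threshold)), roc_curve(scores, y_codes)


def run_protocol(
    ds: SpectraDataset,
    preprocess_cfg: PreprocessConfig | None,
    pls_cfg: PLSConfig,
    protocol_cfg: ProtocolConfig,
) -> list[FoldResult]:
    """Execute the full P x T resampling design on a two-class dataset.

    Preprocessing is per-spectrum, so it is applied once up front; each fold
    then re-balances with a fresh bootstrap draw, splits patient-wise, picks
    the LV count at the first local minimum of the patient-grouped CV RMSE
    curve, fits, and evaluates. Fully reproducible from the config seed.
    """
    if len(ds.class_labels) != 2:
        raise ValueError(f"run_protocol requires exactly 2 classes, got {ds.class_labels}")
    work = preprocess_dataset(ds, preprocess_cfg) if preprocess_cfg is not None else ds
    pos = _positive_label(work, protocol_cfg)
    children = np.random.SeedSequence(protocol_cfg.seed).spawn(protocol_cfg.P * protocol_cfg.T)
    results: list[FoldResult] = []
    for p_i in range(protocol_cfg.P):
        for t_i in range(protocol_cfg.T):
            rng = np.random.default_rng(children[p_i * protocol_cfg.T + t_i])
            try:
                bal = balance_classes(work, protocol_cfg, rng)
                train, test = patient_split(bal, protocol_cfg.train_fraction, rng)
                X_tr = train.intensity_matrix()
                y_tr = (train.label_array() == pos).astype(float)
                max_lv = min(pls_cfg.max_lv, 20, X_tr.shape[0] - pls_cfg.K)
                curve = cv_rmse(X_tr, y_tr, train.patient_array(), max_lv=max_lv, K=pls_cfg.K, rng=rng)
                n_lv = select_n_lv(curve)
                model = fit_pls(X_tr, y_tr, n_lv)
                train_m, train_roc = _evaluate(model, X_tr, y_tr.astype(int), pls_cfg.threshold)
                y_te = (test.label_array() == pos).astype(int)
                test_m, test_roc = _evaluate(model, test.intensity_matrix(), y_te, pls_cfg.threshold)
                vip = vip_scores(model, X_tr, y_tr)
            except ValueError as err:
                raise ValueError(f"fold (p={p_i + 1}, t={t_i + 1}): {err}") from err
            logger.info(
                "fold (p=%d, t=%d): n_lv=%d train_acc=%.3f test_acc=%.3f (train patients=%d, test patients=%d)",
                p_i + 1, t_i + 1, n_lv, train_m.accuracy, test_m.accuracy,
                len(train.class_of_patient), len(test.class_of_patient),
            )
            results.append(
                FoldResult(
                    fold_id=(p_i + 1, t_i + 1),
                    n_lv_used=n_lv,
                    train_metrics=train_m,
                    test_metrics=test_m,
                    train_roc=train_roc,
                    test_roc=test_roc,
                    vip=vip,
                    train_patient_ids=frozenset(train.class_of_patient),
                    test_patient_ids=frozenset(test.class_of_patient),
                )
            )
    return results


def aggregate(
    results: list[FoldResult],
    wavenumbers: np.ndarray | None = None,
    positive_label: str = "positive",
) -> ProtocolSummary:
    """Unweighted mean/min/max per metric per set and the mean VIP profile."""
    if not results:
        raise ValueError("aggregate: no fold results")
    stats: dict[str, dict[str, tuple[float, float, float]]] = {}
    for set_name in ("train", "test"):
        stats[set_name] = {}
        for metric in METRIC_NAMES:
            vals = []
            for r in results:
                if metric == "roc_auc":
                    vals.append(r.train_roc.auc if set_name == "train" else r.test_roc.auc)
                else:
                    fm = r.train_metrics if set_name == "train" else r.test_metrics
                    vals.append(getattr(fm, metric))
            arr = np.asarray(vals, dtype=float)
            stats[set_name][metric] = (float(arr.mean()), float(arr.min()), float(arr.max()))
    mean_vip = np.mean(np.vstack([r.vip for r in results]), axis=0)
    return ProtocolSummary(
        stats=stats,
        mean_vip=mean_vip,
        n_folds=len(results),
        positive_label=positive_label,
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
    )


def vip_band_report(
    summary: ProtocolSummary, peak_library: list[PeakSpec], window_cm1: float = 10.0
) -> pd.DataFrame:
    """Per library band, the maximum mean VIP within +/- window and its
    rank among bands (rank 1 = most important). A zero window reduces to a
    nearest-grid-point lookup."""
    if summary.wavenumbers is None:
        raise ValueError("vip_band_report: summary carries no wavenumber axis")
    grid = summary.wavenumbers
    rows = []
    for peak in peak_library:
        mask = np.abs(grid - peak.center) <= window_cm1
        if not np.any(mask):
            mask = np.zeros_like(grid, dtype=bool)
            mask[int(np.argmin(np.abs(grid - peak.center)))] = True
        rows.append(
            {"band_cm1": peak.center, "assignment": peak.assignment,
             "mean_vip": float(summary.mean_vip[mask].max())}
        )
    table = pd.DataFrame(rows)
    table["rank"] = table["mean_vip"].rank(ascending=False, method="min").astype(int)
    return table.sort_values("rank", kind="mergesort").reset_index(drop=True)
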