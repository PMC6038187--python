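"""Population-constrained cross-validation, accuracy aggregation and subsampling.

The validation design mirrors how genomic selection is stress-tested in
structured germplasm: the validation set (VS) is drawn from one target
population (or a named union of populations, or "All"), partitioned into
``n_folds`` near-equal folds, while the calibration set (CS) always contains
every individual not in the current VS — including all other populations.
Accuracy is the Pearson correlation between observed (BLUP) phenotypes and
predictions, computed per fold and averaged over folds and replications;
MSE likewise.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prediction_models import ModelSpec, fit_model, predict
from .quantitative_genetics import KinshipMatrix, compute_grm

logger = logging.getLogger(__name__)


@dataclass
class CVScheme:
    """Validation-set design: target population(s), folds, replications, seed.

    ``target`` is "All", a single population label, or a name registered in
    ``unions`` (e.g. ``{"Low": ["K", "N1", "N1EM"]}``).
    """

    target: str = "All"
    n_folds: int = 5
    n_replications: int = 20
    seed: int = 0
    unions: dict[str, list[str]] = field(default_factory=dict)

    def target_mask(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        if self.target == "All":
            return np.ones(len(labels), dtype=bool)
        members = self.unions.get(self.target, [self.target])
        mask = np.isin(labels, members)
        if not mask.any():
            raise ValueError(f"target {self.target!r} matches no individuals")
        return mask


def make_folds(scheme: CVScheme, labels: np.ndarray, replication_index: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition the target population into folds; CS = everyone else.

    Returns ``[(cs_idx, vs_idx), ...]`` with VS folds disjoint, of sizes
    differing by at most one, and jointly covering the target population.
    The RNG stream is keyed by (seed, replication, target) so every method
    compared under the same scheme sees identical folds.
    """
    labels = np.asarray(labels)
    mask = scheme.target_mask(labels)
    target_idx = np.flatnonzero(mask)
    if len(target_idx) < scheme.n_folds:
        raise ValueError(
            f"target {scheme.target!r} has {len(target_idx)} individuals; need >= {scheme.n_folds}"
        )
    key = np.random.SeedSequence(
        [scheme.seed, replication_index, zlib.crc32(scheme.target.encode())]
    )
    rng = np.random.default_rng(key)
    perm = rng.permutation(target_idx)
    everyone = np.arange(len(labels))
    folds = []
    for vs in np.array_split(perm, scheme.n_folds):
        vs = np.sort(vs)
        cs = np.setdiff1d(everyone, vs, assume_unique=False)
        folds.append((cs, vs))
    return folds


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Pearson correlation between observed values and predictions.

    Returns NaN (recorded as missing, never zero) when either vector has no
    variance.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return np.nan
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error (1/n) sum (y - yhat)^2 over the validation fold."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))


@dataclass
class CVResult:
    trait: str
    target: str
    method: str
    r: float
    mse: float
    sd_r: float
    records: pd.DataFrame          # one row per replication x fold

    @property
    def n_records(self) -> int:
        return len(self.records)


def run_cv(
    y: np.ndarray,
    labels: np.ndarray,
    scheme: CVScheme,
    model_spec: ModelSpec,
    X: np.ndarray | None = None,
    K: KinshipMatrix | None = None,
    trait: str = "trait",
) -> CVResult:
    """Replicated, population-constrained k-fold CV for one trait and method.

    For each replication x fold the model is refitted on the CS (variance
    components included) and the VS phenotypes are masked and predicted.
    Per-fold r and MSE are averaged over all folds and replications; a fold
    where the model fails is recorded and excluded with a warning, never
    silently imputed.
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    if len(y) != len(labels):
        raise ValueError("y and labels must align")
    rows = []
    for rep in range(scheme.n_replications):
        for fold_i, (cs, vs) in enumerate(make_folds(scheme, labels, rep)):
            try:
                model = fit_model(model_spec, y, X=X, K=K, train_idx=cs)
                if model_spec.method == "KINBLUP":
                    pred = predict(model, idx=vs)
                else:
                    pred = predict(model, X=X[vs])
            except Exception as err:  # noqa: BLE001 - fold failure is data, not control flow
                warnings.warn(f"fold {fold_i} of replication {rep} failed: {err}")
                continue
            rows.append(
                {
                    "replication": rep,
                    "fold": fold_i,
                    "n_vs": len(vs),
                    "r": accuracy(y[vs], pred),
                    "mse": mse(y[vs], pred),
                }
            )
    records = pd.DataFrame(rows)
    return CVResult(
        trait=trait,
        target=scheme.target,
        method=model_spec.method,
        r=float(records["r"].mean()) if len(records) else np.nan,
        mse=float(records["mse"].mean()) if len(records) else np.nan,
        sd_r=float(records["r"].std(ddof=1)) if len(records) > 1 else np.nan,
        records=records,
    )


def screen_traits(results: list[CVResult], threshold: float = 0.5) -> list[str]:
    """Traits whose unconstrained ("All") kin-BLUP accuracy strictly exceeds the threshold."""
    keep = []
    for res in results:
        if res.method == "KINBLUP" and res.target == "All" and np.isfinite(res.r) and res.r > threshold:
            if res.trait not in keep:
                keep.append(res.trait)
    return keep


@dataclass
class SubsamplingResult:
    axis: str
    levels: list[int]
    mean_r: list[float]
    sd_r: list[float]
    records: pd.DataFrame


def subsample_experiment(
    y: np.ndarray,
    labels: np.ndarray,
    dosage: np.ndarray,
    axis: str,
    levels: list[int],
    scheme: CVScheme,
    model_spec: ModelSpec,
    seed: int = 0,
) -> SubsamplingResult:
    """Accuracy as a function of marker count or calibration-set size.

    For each level, markers (``axis="n_snps"``) or individuals
    (``axis="n_individuals"``) are randomly subsampled (seeded per level),
    the relationship matrix is rebuilt from the subsample, and the scheme's
    CV is rerun.  Levels must not exceed availability.
    """
    if axis not in ("n_snps", "n_individuals"):
        raise ValueError("axis must be 'n_snps' or 'n_individuals'")
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    n, m = dosage.shape
    levels = sorted(int(v) for v in levels)
    limit = m if axis == "n_snps" else n
    if levels[-1] > limit:
        raise ValueError(f"level {levels[-1]} exceeds available {axis} ({limit})")

    from .genotype_qc import SNP_COLUMNS, GenotypeMatrix

    all_rows = []
    mean_r, sd_r = [], []
    for li, level in enumerate(levels):
        rng = np.random.default_rng(np.random.SeedSequence([seed, li, level]))
        if axis == "n_snps":
            cols = np.sort(rng.choice(m, size=level, replace=False)) if level < m else np.arange(m)
            sub_dosage, sub_y, sub_labels = dosage[:, cols], y, labels
        else:
            rows_idx = np.sort(rng.choice(n, size=level, replace=False)) if level < n else np.arange(n)
            sub_dosage, sub_y, sub_labels = dosage[rows_idx], y[rows_idx], labels[rows_idx]
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(sub_dosage.shape[1])],
                "chrom": "chr1",
                "pos": np.arange(1, sub_dosage.shape[1] + 1),
                "ref": "A",
                "alt": "C",
            }
        )[SNP_COLUMNS]
        g = GenotypeMatrix(
            samples=[f"i{i}" for i in range(sub_dosage.shape[0])], snps=snp_map, dosage=sub_dosage
        )
        K = compute_grm(g)
        res = run_cv(sub_y, sub_labels, scheme, model_spec, X=sub_dosage, K=K)
        rec = res.records.assign(level=level)
        all_rows.append(rec)
        mean_r.append(res.r)
        sd_r.append(float(res.records["r"].std(ddof=1)) if len(res.records) > 1 else np.nan)
    return SubsamplingResult(
        axis=axis, levels=levels, mean_r=mean_r, sd_r=sd_r, records=pd.concat(all_rows, ignore_index=True)
    )


def results_table(results: list[CVResult]) -> pd.DataFrame:
    """Long summary: one row per trait x target x method."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait, "target": r.target, "method": r.method,
                "r": r.r, "mse": r.mse, "sd_r": r.sd_r, "n_records": r.n_records,
            }
            for r in results
        ]
    )
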