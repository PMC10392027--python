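"""Expression normalization, batch adjustment, gene filtering and frozen
transformation parameters.

The transformation chain fitted on the training cohort is
log2-CPM -> expression-fraction gene filter -> per-gene location-scale batch
adjustment -> per-gene z-score. Every parameter learned in that chain is
frozen into :class:`PreprocessParams` so that validation cohorts are
transformed with *training* statistics only — the prospective-validation
contract: no statistic of a validation cohort may ever flow back into the
parameters. Batches unseen at fit time are left unadjusted (logged), since
no frozen offset exists for them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._containers import ExpressionMatrix

__all__ = [
    "PreprocessParams",
    "normalize",
    "adjust_batches",
    "filter_genes",
    "apply_frozen",
    "fit_preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Frozen per-gene transformation parameters learned on training data.

    ``center``/``scale`` are the z-scoring statistics on the normalized,
    batch-adjusted scale. ``batch_means``/``batch_ratios`` hold, for each
    training batch, the per-gene batch mean and the pooled-SD/batch-SD ratio
    of the location-scale adjustment; ``pooled_mean`` is the per-gene grand
    mean the adjustment re-centers onto.
    """

    kept_gene_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    batch_means: dict[str, np.ndarray] = field(default_factory=dict)
    batch_ratios: dict[str, np.ndarray] = field(default_factory=dict)
    pooled_mean: np.ndarray | None = None
    library_method: str = "log2-cpm"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (len(self.kept_gene_ids) == len(self.center) == len(self.scale)):
            raise ValueError("kept genes, centers and scales must align")
        if np.any(self.scale <= 0):
            raise ValueError("every per-gene scale must be positive")

    def content_hash(self) -> str:
        payload = {
            "genes": self.kept_gene_ids,
            "center": [repr(float(c)) for c in self.center],
            "scale": [repr(float(s)) for s in self.scale],
            "pooled": [repr(float(m)) for m in self.pooled_mean]
            if self.pooled_mean is not None
            else None,
            "batches": {
                b: [repr(float(v)) for v in self.batch_means[b]]
                for b in sorted(self.batch_means)
            },
            "ratios": {
                b: [repr(float(v)) for v in self.batch_ratios[b]]
                for b in sorted(self.batch_ratios)
            },
            "method": self.library_method,
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()


def normalize(expr: ExpressionMatrix, *, on_normalized: str = "error") -> ExpressionMatrix:
    """Counts-per-million then log2(x + 1), per sample.

    ``on_normalized`` controls behaviour when the input is already flagged
    normalized: 'error' (default) or 'passthrough'. The transform is never
    applied twice.
    """
    if expr.is_normalized:
        if on_normalized == "passthrough":
            return expr
        raise ValueError("input is already normalized; refusing to double-transform")
    sums = expr.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if len(zero):
        raise ValueError(
            f"sample {expr.sample_ids[zero[0]]!r} has all-zero expression"
        )
    cpm = expr.values / sums[None, :] * 1e6
    return replace(expr, values=np.log2(cpm + 1.0), is_normalized=True)


def _batch_stats(values: np.ndarray, batches: np.ndarray, levels: list[str]):
    pooled_mean = values.mean(axis=1)
    pooled_sd = values.std(axis=1)
    means, ratios = {}, {}
    for b in levels:
        cols = batches == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        m = values[:, cols].mean(axis=1)
        s = values[:, cols].std(axis=1)
        means[b] = m
        ratios[b] = np.divide(pooled_sd, s, out=np.ones_like(s), where=s > 0)
    return pooled_mean, means, ratios


def adjust_batches(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, dict]:
    """Per-gene location-scale batch adjustment.

    Within each batch, each gene is centered at its batch mean, rescaled so
    the batch standard deviation equals the pooled (all-sample) standard
    deviation, and shifted to the pooled mean. After adjustment, per-gene
    batch means agree to numerical precision. Returns the adjusted matrix
    and the frozen adjustment statistics.
    """
    if not expr.is_normalized:
        raise ValueError("adjust_batches expects normalized input")
    if expr.batch is None or len(set(expr.batch)) == 1:
        return expr, {"pooled_mean": None, "batch_means": {}, "batch_ratios": {}}
    batches = np.asarray(expr.batch)
    levels = sorted(set(batches))
    pooled_mean, means, ratios = _batch_stats(expr.values, batches, levels)
    values = expr.values.copy()
    for b in levels:
        cols = batches == b
        values[:, cols] = (values[:, cols] - means[b][:, None]) * ratios[b][:, None] \
            + pooled_mean[:, None]
    stats = {"pooled_mean": pooled_mean, "batch_means": means, "batch_ratios": ratios}
    return replace(expr, values=values), stats


def filter_genes(expr: ExpressionMatrix, min_frac_expressed: float = 0.2) -> ExpressionMatrix:
    """Keep genes detected (value > 0) in at least ``min_frac_expressed`` of samples."""
    if not expr.is_normalized:
        raise ValueError("filter_genes expects normalized input")
    frac = (expr.values > 0).mean(axis=1)
    keep = frac >= min_frac_expressed
    if not keep.any():
        raise ValueError("gene filter removed every gene; lower min_frac_expressed")
    kept = [g for g, k in zip(expr.gene_ids, keep) if k]
    return expr.subset_genes(kept)


def fit_preprocess(
    expr: ExpressionMatrix, min_frac_expressed: float = 0.2
) -> tuple[ExpressionMatrix, PreprocessParams]:
    """Training-cohort chain: normalize, filter, batch-adjust, z-score.

    Constant genes (zero variance after adjustment) are dropped with a
    warning — they carry no information for any survival model.
    """
    x = normalize(expr, on_normalized="passthrough")
    x = filter_genes(x, min_frac_expressed)
    x, bstats = adjust_batches(x)
    center = x.values.mean(axis=1)
    scale = x.values.std(axis=1)
    degenerate = scale <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant gene(s) dropped before z-scoring",
            RuntimeWarning,
            stacklevel=2,
        )
        keep = ~degenerate
        kept = [g for g, k in zip(x.gene_ids, keep) if k]
        x = x.subset_genes(kept)
        center, scale = center[keep], scale[keep]
        bstats = {
            "pooled_mean": bstats["pooled_mean"][keep]
            if bstats["pooled_mean"] is not None
            else None,
            "batch_means": {b: v[keep] for b, v in bstats["batch_means"].items()},
            "batch_ratios": {b: v[keep] for b, v in bstats["batch_ratios"].items()},
        }
    params = PreprocessParams(
        kept_gene_ids=list(x.gene_ids),
        center=center,
        scale=scale,
        batch_means=bstats["batch_means"],
        batch_ratios=bstats["batch_ratios"],
        pooled_mean=bstats["pooled_mean"],
    )
    z = (x.values - center[:, None]) / scale[:, None]
    return replace(x, values=z), params


def apply_frozen(
    expr: ExpressionMatrix,
    params: PreprocessParams,
    *,
    max_missing_frac: float = 0.2,
) -> ExpressionMatrix:
    """Transform a cohort with training parameters only.

    Normalizes (if raw), selects the training gene list, applies the frozen
    batch adjustment for batches seen at fit time, and z-scores with frozen
    center/scale. Genes absent from the new cohort are filled at the
    training center (z = 0) with a warning; more than ``max_missing_frac``
    missing genes is an error. No statistic of ``expr`` alters ``params``.
    """
    x = normalize(expr, on_normalized="passthrough")
    idx = x.gene_index()
    missing = [g for g in params.kept_gene_ids if g not in idx]
    if len(missing) > max_missing_frac * len(params.kept_gene_ids):
        raise ValueError(
            f"{len(missing)} of {len(params.kept_gene_ids)} frozen genes "
            "missing from the cohort (exceeds tolerance)"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} frozen gene(s) missing; filled at training center",
            RuntimeWarning,
            stacklevel=2,
        )
        log.warning("missing genes filled at center: %s", missing[:10])
    n = x.n_samples
    g = len(params.kept_gene_ids)
    vals = np.empty((g, n))
    present_rows = []
    for row, gene in enumerate(params.kept_gene_ids):
        if gene in idx:
            vals[row] = x.values[idx[gene]]
            present_rows.append(row)
        else:
            vals[row] = params.center[row]
    present_rows = np.asarray(present_rows, dtype=int)
    if params.batch_means and x.batch is not None:
        batches = np.asarray(x.batch)
        known = set(params.batch_means)
        unknown = sorted(set(batches) - known)
        if unknown:
            log.info("batches %s unseen at fit time; left unadjusted", unknown)
        for b in sorted(set(batches) & known):
            cols = batches == b
            block = vals[np.ix_(present_rows, np.flatnonzero(cols))]
            m = params.batch_means[b][present_rows, None]
            r = params.batch_ratios[b][present_rows, None]
            pm = params.pooled_mean[present_rows, None]
            vals[np.ix_(present_rows, np.flatnonzero(cols))] = (block - m) * r + pm
    z = (vals - params.center[:, None]) / params.scale[:, None]
    return ExpressionMatrix(
        gene_ids=list(params.kept_gene_ids),
        sample_ids=list(x.sample_ids),
        values=z,
        batch=list(x.batch) if x.batch is not None else None,
        is_normalized=True,
    )
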