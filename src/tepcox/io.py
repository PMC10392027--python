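"""Plain-text readers and writers for every pipeline artifact.

Expression travels as tab-separated text (first column the gene id, header
row of sample ids), clinical tables as comma-separated text with the
documented header, and all fitted parameters (preprocessing statistics,
signatures, nomograms, reports) as diff-able text: CSV or versioned JSON.
Floats in parameter files are serialized via ``repr`` / C99 hex so round
trips are bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._containers import CLINICAL_COLUMNS, ClinicalTable, ExpressionMatrix
from .preprocess import PreprocessParams
from .screening import GeneSignature
from .synthetic import SyntheticTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "write_truth",
    "read_truth",
    "write_params",
    "read_params",
    "write_signature",
    "read_signature",
    "write_scores",
    "read_scores",
]

_PARAMS_VERSION = 1


def read_expression(path, batch=None, is_normalized=False) -> ExpressionMatrix:
    """Read a genes x samples matrix from tab- or comma-separated text."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene row {dup!r} in {path}")
    if df.isna().any().any():
        cells = [
            f"({g}, {s})"
            for g, row in df.iterrows()
            for s in df.columns[row.isna()]
        ]
        raise ValueError(f"missing values in {path} at {cells[:5]}")
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        batch=batch,
        is_normalized=is_normalized,
    )


def write_expression(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id",
                           float_format="%.17g")


def read_clinical(path) -> ClinicalTable:
    """Read the per-sample clinical table; types are validated on load."""
    df = pd.read_csv(path)
    df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in clinical.data.columns]
    cols += [c for c in clinical.data.columns if c not in cols]
    clinical.data[cols].to_csv(path, index=False, float_format="%.12g")


def write_truth(truth: SyntheticTruth, path) -> None:
    """Ground-truth sidecar as key: value text."""
    lines = [
        "format: tepcox-truth v1",
        f"baseline_shape: {truth.baseline_params[0]!r}",
        f"baseline_scale: {truth.baseline_params[1]!r}",
        "signal_genes: " + ",".join(truth.signal_gene_ids),
        "true_betas: " + ",".join(repr(float(b)) for b in truth.true_betas),
        "true_linear_predictor: "
        + ",".join(repr(float(v)) for v in truth.true_linear_predictor),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path) -> SyntheticTruth:
    fields = {}
    for line in Path(path).read_text().splitlines():
        key, _, val = line.partition(": ")
        fields[key] = val
    if fields.get("format") != "tepcox-truth v1":
        raise ValueError(f"{path} is not a truth sidecar")
    genes = fields["signal_genes"].split(",") if fields["signal_genes"] else []
    betas = (
        [float(v) for v in fields["true_betas"].split(",")]
        if fields["true_betas"]
        else []
    )
    return SyntheticTruth(
        signal_gene_ids=genes,
        true_betas=np.asarray(betas),
        baseline_params=(
            float(fields["baseline_shape"]),
            float(fields["baseline_scale"]),
        ),
        true_linear_predictor=np.array(
            [float(v) for v in fields["true_linear_predictor"].split(",")]
        ),
    )


def write_params(params: PreprocessParams, path) -> None:
    payload = {
        "format": "tepcox-preprocess-params",
        "version": _PARAMS_VERSION,
        "library_method": params.library_method,
        "kept_gene_ids": params.kept_gene_ids,
        "center": [float(v).hex() for v in params.center],
        "scale": [float(v).hex() for v in params.scale],
        "pooled_mean": [float(v).hex() for v in params.pooled_mean]
        if params.pooled_mean is not None
        else None,
        "batch_means": {
            b: [float(v).hex() for v in arr] for b, arr in params.batch_means.items()
        },
        "batch_ratios": {
            b: [float(v).hex() for v in arr] for b, arr in params.batch_ratios.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_params(path) -> PreprocessParams:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "tepcox-preprocess-params":
        raise ValueError(f"{path} is not a preprocessing-parameter file")
    if payload.get("version") != _PARAMS_VERSION:
        raise ValueError(f"unsupported parameter file version {payload.get('version')}")
    unhex = lambda xs: np.array([float.fromhex(x) for x in xs])
    return PreprocessParams(
        kept_gene_ids=list(payload["kept_gene_ids"]),
        center=unhex(payload["center"]),
        scale=unhex(payload["scale"]),
        pooled_mean=unhex(payload["pooled_mean"])
        if payload["pooled_mean"] is not None
        else None,
        batch_means={b: unhex(v) for b, v in payload["batch_means"].items()},
        batch_ratios={b: unhex(v) for b, v in payload["batch_ratios"].items()},
        library_method=payload["library_method"],
    )


def write_signature(sig: GeneSignature, path) -> None:
    df = sig.to_frame()
    header = (
        f"# tepcox-signature v1 lambda={sig.lambda_used!r} "
        + " ".join(f"{k}={v}" for k, v in sorted(sig.meta.items()))
        + "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.17g")


def read_signature(path) -> GeneSignature:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# tepcox-signature v1"):
            raise ValueError(f"{path} is not a signature file")
        lam = float(header.split("lambda=")[1].split()[0])
        df = pd.read_csv(fh)
    return GeneSignature(
        gene_ids=[str(g) for g in df["gene_id"]],
        uni_beta=df["uni_beta"].to_numpy(),
        uni_se=df["uni_se"].to_numpy(),
        uni_p=df["uni_p"].to_numpy(),
        lasso_beta=df["lasso_beta"].to_numpy(),
        lambda_used=lam,
    )


def write_scores(scores, path) -> None:
    pd.DataFrame({"sample_id": scores.sample_ids, "risk_score": scores.score}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_scores(path):
    from .network import RiskScores

    df = pd.read_csv(path)
    return RiskScores(
        sample_ids=[str(s) for s in df["sample_id"]],
        score=df["risk_score"].to_numpy(),
    )
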