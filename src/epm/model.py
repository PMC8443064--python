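"""Linear models of gene expression from histone-modification signal.

The response is y = log2(FPKM + 0.1) and the predictors are
x_j = log2(signal_j + 0.1) for each histone mark quantified at the
regulatory region linked to the gene, fitted by ordinary least squares:

    y_i ~ b0 + b1 x_i1 + ... + bn x_in + eps

For enhancer models a gene enters the dataset once per associated
enhancer, so highly connected genes weigh more.  Variable importance is
the absolute t-statistic of each coefficient; model performance is the
Pearson correlation between predicted and measured y on held-out rows.
Randomized controls refit the same model after shuffling expression over
all genes, and cross-context evaluation fits on one cellular context's
full dataset and scores on every other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .intervals import SchemaError

__all__ = [
    "PSEUDOCOUNT",
    "ModelDataset",
    "FittedModel",
    "EvaluationResult",
    "PairedTTest",
    "assemble_dataset",
    "shuffle_expression",
    "split_train_test",
    "fit_linear_model",
    "predict",
    "evaluate",
    "cross_validate",
    "cross_context_matrix",
    "paired_t_test",
    "significance_stars",
]

PSEUDOCOUNT = 0.1


@dataclass
class ModelDataset:
    """Rows of (gene, region, y, predictors) ready for regression."""

    frame: pd.DataFrame  # columns: gene_id, region_id, y, *marks
    marks: list[str]
    context: str | None = None

    def __post_init__(self) -> None:
        required = {"gene_id", "region_id", "y", *self.marks}
        missing = required - set(self.frame.columns)
        if missing:
            raise SchemaError(f"dataset missing columns {sorted(missing)}")
        if not np.isfinite(self.frame[["y", *self.marks]].to_numpy()).all():
            raise ValueError("dataset contains non-finite values")

    @property
    def genes(self) -> np.ndarray:
        return self.frame["gene_id"].unique()

    def __len__(self) -> int:
        return len(self.frame)

    def subset_genes(self, genes: Iterable[str]) -> "ModelDataset":
        keep = self.frame["gene_id"].isin(set(genes))
        return ModelDataset(self.frame.loc[keep].copy(), list(self.marks), self.context)

    def without_marks(self, excluded: Iterable[str]) -> "ModelDataset":
        excluded = set(excluded)
        marks = [m for m in self.marks if m not in excluded]
        if not marks:
            raise ValueError("cannot exclude every predictor")
        cols = ["gene_id", "region_id", "y", *marks]
        return ModelDataset(self.frame[cols].copy(), marks, self.context)


@dataclass
class FittedModel:
    """OLS fit with per-coefficient t-statistics and importance shares.

    ``importance`` is |t| per predictor (intercept excluded); ``shares``
    normalizes importance to sum to 1 over predictors with finite t.  For
    an exactly interpolating fit (zero residual variance) t is undefined
    and flagged infinite rather than reported as a number.
    """

    marks: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_scale: float
    n_obs: int
    zero_residual: bool = False
    context: str | None = None

    @property
    def importance(self) -> pd.Series:
        return self.tvalues[self.marks].abs()

    @property
    def shares(self) -> pd.Series:
        imp = self.importance
        finite = imp[np.isfinite(imp)]
        shares = pd.Series(0.0, index=imp.index)
        if finite.sum() > 0:
            shares[finite.index] = finite / finite.sum()
        return shares

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "n_obs": int(self.n_obs),
            "zero_residual": bool(self.zero_residual),
            "resid_scale": float(self.resid_scale),
            "coefficients": self.params.to_dict(),
            "t": {k: (None if not np.isfinite(v) else v) for k, v in self.tvalues.items()},
            "p": {k: (None if not np.isfinite(v) else v) for k, v in self.pvalues.items()},
            "importance_share": self.shares.to_dict(),
        }


@dataclass
class EvaluationResult:
    r: float
    n: int
    predictions: pd.DataFrame  # gene_id, region_id, predicted, measured
    degenerate: bool = False


@dataclass
class PairedTTest:
    t: float
    df: int
    p_value: float
    stars: str
    degenerate: bool = False


def assemble_dataset(
    expression: pd.Series,
    signal: pd.DataFrame,
    associations: pd.DataFrame,
    marks: Sequence[str],
    region_col: str | None = None,
    pseudocount: float = PSEUDOCOUNT,
    gene_filter: Iterable[str] | None = None,
    context: str | None = None,
) -> ModelDataset:
    """Join expression, per-region signal and gene-region links into rows.

    ``associations`` needs columns ``gene_id`` and a region id column
    (``enhancer_id`` or ``promoter_id``, auto-detected when not given).
    One row is emitted per distinct (gene, region) pair, so genes linked to
    several enhancers are duplicated — once per enhancer.  Genes outside
    ``gene_filter`` (e.g. non-protein-coding) are dropped; genes without
    any association are simply absent.  A region missing from the signal
    matrix is an error.
    """
    marks = list(marks)
    missing_marks = [m for m in marks if m not in signal.columns]
    if missing_marks:
        raise SchemaError(f"signal matrix missing marks {missing_marks}")
    if region_col is None:
        for cand in ("enhancer_id", "promoter_id", "region_id"):
            if cand in associations.columns:
                region_col = cand
                break
        else:
            raise SchemaError("associations need enhancer_id/promoter_id/region_id")
    pairs = associations[["gene_id", region_col]].drop_duplicates()
    pairs = pairs[pairs["gene_id"].isin(expression.index)]
    if gene_filter is not None:
        pairs = pairs[pairs["gene_id"].isin(set(gene_filter))]
    missing_regions = set(pairs[region_col]) - set(signal.index)
    if missing_regions:
        raise SchemaError(
            f"signal matrix missing {len(missing_regions)} regions, "
            f"e.g. {sorted(missing_regions)[:3]}"
        )
    y = np.log2(expression.loc[pairs["gene_id"]].to_numpy(dtype=float) + pseudocount)
    x = np.log2(
        signal.loc[pairs[region_col], marks].to_numpy(dtype=float) + pseudocount
    )
    frame = pd.DataFrame(
        {"gene_id": pairs["gene_id"].to_numpy(), "region_id": pairs[region_col].to_numpy(), "y": y}
    )
    frame[marks] = x
    frame = frame.sort_values(["gene_id", "region_id"], ignore_index=True)
    return ModelDataset(frame, marks, context)


def shuffle_expression(expression: pd.Series, seed: int) -> pd.Series:
    """Permute expression values over all genes, keeping gene ids fixed."""
    rng = np.random.default_rng(seed)
    values = expression.to_numpy(copy=True)
    rng.shuffle(values)
    return pd.Series(values, index=expression.index, name=expression.name)


def split_train_test(
    dataset: ModelDataset,
    train_frac: float = 0.8,
    seed: int = 0,
    level: str = "gene",
) -> tuple[ModelDataset, ModelDataset]:
    """Seeded train/test split.

    ``level="gene"`` (default) splits at the gene level so the duplicated
    rows of one gene never straddle the split; ``level="row"`` splits rows
    directly (kept for fidelity experiments, leaks duplicated y values).
    """
    rng = np.random.default_rng(seed)
    if level == "gene":
        genes = np.sort(dataset.genes)
        if len(genes) < 10:
            raise ValueError("need at least 10 genes to split")
        n_train = int(round(train_frac * len(genes)))
        train_genes = rng.choice(genes, size=n_train, replace=False)
        train = dataset.subset_genes(train_genes)
        test = dataset.subset_genes(np.setdiff1d(genes, train_genes))
        return train, test
    if level == "row":
        n = len(dataset)
        idx = rng.permutation(n)
        n_train = int(round(train_frac * n))
        tr = dataset.frame.iloc[np.sort(idx[:n_train])].copy()
        te = dataset.frame.iloc[np.sort(idx[n_train:])].copy()
        return (
            ModelDataset(tr, list(dataset.marks), dataset.context),
            ModelDataset(te, list(dataset.marks), dataset.context),
        )
    raise ValueError(f"level must be gene|row, got {level!r}")


def fit_linear_model(dataset: ModelDataset) -> FittedModel:
    """Ordinary least squares of y on the mark predictors plus intercept."""
    x = dataset.frame[dataset.marks].to_numpy(dtype=float)
    y = dataset.frame["y"].to_numpy(dtype=float)
    if len(y) <= len(dataset.marks) + 1:
        raise ValueError("need more rows than predictors + 1")
    if np.any(x.std(axis=0) == 0):
        flat = [m for m, s in zip(dataset.marks, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant predictor column(s): {flat}")
    design = sm.add_constant(x)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns involved in the collinearity via the null space
        _, _, vt = np.linalg.svd(design)
        null = np.abs(vt[-1][1:])
        guilty = [m for m, w in zip(dataset.marks, null) if w > 1e-8]
        raise ValueError(f"rank-deficient design; collinear predictors: {guilty}")
    res = sm.OLS(y, design).fit()
    names = ["const", *dataset.marks]
    params = pd.Series(res.params, index=names)
    zero_resid = res.ssr <= max(1e-12, 1e-12 * float(np.sum(y**2)))
    if zero_resid:
        tvalues = pd.Series(np.inf, index=names)
        pvalues = pd.Series(0.0, index=names)
        bse = pd.Series(0.0, index=names)
        scale = 0.0
    else:
        tvalues = pd.Series(res.tvalues, index=names)
        pvalues = pd.Series(res.pvalues, index=names)
        bse = pd.Series(res.bse, index=names)
        scale = float(np.sqrt(res.scale))
    return FittedModel(
        marks=list(dataset.marks),
        params=params,
        bse=bse,
        tvalues=tvalues,
        pvalues=pvalues,
        resid_scale=scale,
        n_obs=len(y),
        zero_residual=zero_resid,
        context=dataset.context,
    )


def predict(model: FittedModel, dataset: ModelDataset) -> np.ndarray:
    missing = [m for m in model.marks if m not in dataset.frame.columns]
    if missing:
        raise SchemaError(f"dataset missing model predictors {missing}")
    x = dataset.frame[model.marks].to_numpy(dtype=float)
    return model.params["const"] + x @ model.params[model.marks].to_numpy()


def evaluate(model: FittedModel, dataset: ModelDataset) -> EvaluationResult:
    """Pearson r between predicted and measured y over rows (each
    duplicated gene row contributes one term)."""
    yhat = predict(model, dataset)
    y = dataset.frame["y"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows to evaluate")
    preds = pd.DataFrame(
        {
            "gene_id": dataset.frame["gene_id"].to_numpy(),
            "region_id": dataset.frame["region_id"].to_numpy(),
            "predicted": yhat,
            "measured": y,
        }
    )
    if np.std(yhat) == 0 or np.std(y) == 0:
        return EvaluationResult(r=np.nan, n=len(y), predictions=preds, degenerate=True)
    r = float(stats.pearsonr(yhat, y).statistic)
    return EvaluationResult(r=r, n=len(y), predictions=preds)


def cross_validate(
    dataset: ModelDataset,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated k-fold cross-validation at the gene level.

    Returns one row per (repeat, fold) with the fold's evaluation r;
    within each repeat every gene appears in exactly one test fold.
    """
    genes = np.sort(dataset.genes)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(repeats):
        perm = rng.permutation(genes)
        folds = np.array_split(perm, k)
        for fold_idx, fold_genes in enumerate(folds):
            test = dataset.subset_genes(fold_genes)
            train = dataset.subset_genes(np.setdiff1d(genes, fold_genes))
            model = fit_linear_model(train)
            result = evaluate(model, test)
            records.append(
                {"repeat": rep, "fold": fold_idx, "r": result.r, "n_test": result.n}
            )
    return pd.DataFrame(records)


def cross_context_matrix(
    datasets: Mapping[str, ModelDataset],
    marks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Train on each context's full dataset, evaluate on every other.

    Returns a train-context x eval-context matrix of Pearson r with an
    empty (NaN) diagonal.
    """
    contexts = list(datasets)
    if len(contexts) < 2:
        raise ValueError("need at least 2 contexts")
    if marks is not None:
        datasets = {
            c: d.without_marks(set(d.marks) - set(marks)) for c, d in datasets.items()
        }
    matrix = pd.DataFrame(np.nan, index=contexts, columns=contexts)
    for train_ctx in contexts:
        model = fit_linear_model(datasets[train_ctx])
        for eval_ctx in contexts:
            if eval_ctx == train_ctx:
                continue
            matrix.loc[train_ctx, eval_ctx] = evaluate(model, datasets[eval_ctx]).r
    matrix.index.name = "train"
    matrix.columns.name = "eval"
    return matrix


def significance_stars(p: float) -> str:
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def paired_t_test(
    model_rs: Sequence[float], random_rs: Sequence[float]
) -> PairedTTest:
    """Classical paired t-test of model vs randomized-control performance,
    paired by evaluation set."""
    a = np.asarray(model_rs, dtype=float)
    b = np.asarray(random_rs, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length lists of >= 2 paired values")
    d = a - b
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        return PairedTTest(t=np.nan, df=n - 1, p_value=np.nan, stars="ns", degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return PairedTTest(t=t, df=n - 1, p_value=p, stars=significance_stars(p))
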