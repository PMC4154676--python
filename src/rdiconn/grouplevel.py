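"""Edge-wise second-level GLMs with the Regional Displacement Interaction.

For every connection (A, B) the Fisher-Z connectivity strength across
subjects is modelled as a Gaussian GLM.  The baseline ("STD") model is

    Z_AB = b0 + b1*GRP + b2*age + b3*IQ + b4*gender + b5*meanFD + e

and the RDI-augmented model ("STD+RDI") appends the per-region motion
covariates of the two endpoint regions and their interaction:

    ... + b6*dRD_A + b7*dRD_B + b8*(dRD_A * dRD_B)

where dRD_r is the temporal average of regional minus frame-wise
displacement.  Because the models are nested, an F-test on the three RDI
terms measures whether voxel-wise motion pattern explains connectivity
variance beyond the standard covariates.  A Gaussian GLM fitted by IWLS
reduces to ordinary least squares, which is what is computed here (the
statsmodels GLM route is used as an independent cross-check in the test
suite).  Effects of interest are reported as t = beta/SE with two-sided
p-values; multiple testing across edges is controlled by Benjamini-Hochberg
FDR, and thresholded results form statistical parametric networks (SPNs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PhenotypeTable",
    "EdgeModelResult",
    "SPN",
    "MODELS",
    "build_design_matrix",
    "fit_edge_glm",
    "ftest_rdi",
    "pooled_rdi_model",
    "vif_of_interest",
    "fdr_control",
    "build_spn",
]

MODELS = ("STD", "STD+RDI", "STD-GRP", "STD+RDI-GRP")

STD_COLUMNS = ["intercept", "grp", "age", "iq", "gender", "mean_fd"]
RDI_COLUMNS = ["drd_a", "drd_b", "drd_ab"]


@dataclass
class PhenotypeTable:
    """Per-subject phenotypes and motion summaries entering the GLMs.

    ``frame`` columns: subject, group (0/1 dummy, 0 = control), age (years),
    iq, gender (0/1), mean_fd (mm).  ``delta_rd`` is the (n_subjects,
    n_regions) matrix of per-region dRD values aligned with ``frame`` rows.
    """

    frame: pd.DataFrame
    delta_rd: np.ndarray

    def __post_init__(self) -> None:
        required = {"subject", "group", "age", "iq", "gender", "mean_fd"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"phenotype table missing columns {sorted(missing)}")
        modelled = self.frame[["group", "age", "iq", "gender", "mean_fd"]]
        if modelled.isna().any().any():
            raise ValueError("missing values among modelled covariates")
        groups = np.unique(self.frame["group"])
        if len(groups) != 2:
            raise ValueError("group must have exactly 2 levels")
        self.delta_rd = np.asarray(self.delta_rd, dtype=float)
        if self.delta_rd.shape[0] != len(self.frame):
            raise ValueError("delta_rd rows must match phenotype rows")

    @property
    def n_subjects(self) -> int:
        return len(self.frame)


@dataclass
class EdgeModelResult:
    """Per-edge GLM fits for one model specification."""

    model: str
    table: pd.DataFrame          # region_a, region_b, beta, se, t, p, rss, dof, vif
    coefs: np.ndarray            # (n_edges, p) full coefficient vectors
    columns: list[str]
    interest: str                # label of the effect-of-interest column


@dataclass
class SPN:
    """Thresholded differential statistical parametric network."""

    edges: pd.DataFrame
    rule: str                    # e.g. "p<0.01" or "q<0.05"
    n_edges_total: int

    @property
    def n_significant(self) -> int:
        return len(self.edges)

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_edge(
                row["region_a"], row["region_b"],
                t=float(row.get("t", np.nan)), p=float(row["p"]),
            )
        nx.write_graphml(g, str(path))


def _std_design(pheno: PhenotypeTable, include_group: bool) -> tuple[np.ndarray, list[str]]:
    f = pheno.frame
    cols = [np.ones(len(f))]
    labels = ["intercept"]
    if include_group:
        cols.append(f["group"].to_numpy(float))
        labels.append("grp")
    cols += [
        f["age"].to_numpy(float),
        f["iq"].to_numpy(float),
        f["gender"].to_numpy(float),
        f["mean_fd"].to_numpy(float),
    ]
    labels += ["age", "iq", "gender", "mean_fd"]
    return np.column_stack(cols), labels


def build_design_matrix(
    pheno: PhenotypeTable, model: str, pair: tuple[int, int] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for one edge under *model*.

    *pair* holds the region indices (into ``pheno.delta_rd`` columns) of the
    edge's endpoints; required for the RDI models.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    include_group = "-GRP" not in model
    X, labels = _std_design(pheno, include_group)
    if "RDI" in model:
        if pair is None:
            raise ValueError("RDI models need the edge's region pair")
        a, b = pair
        da = pheno.delta_rd[:, a]
        db = pheno.delta_rd[:, b]
        X = np.column_stack([X, da, db, da * db])
        labels = labels + RDI_COLUMNS
    return X, labels


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """OLS via normal equations with pinv; returns (beta, rss, cov_unscaled)."""
    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss, XtX_inv


def fit_edge_glm(
    z: np.ndarray,
    pairs: list[tuple[int, int]],
    pheno: PhenotypeTable,
    model: str = "STD",
) -> EdgeModelResult:
    """Fit the chosen GLM for every edge.

    Parameters
    ----------
    z:
        (n_subjects, n_edges) matrix of Fisher-Z values.
    pairs:
        Per-edge (region_index_a, region_index_b) tuples indexing the
        columns of ``pheno.delta_rd``.
    model:
        One of ``STD``, ``STD+RDI`` (effect of interest: group) or
        ``STD-GRP``, ``STD+RDI-GRP`` (effect of interest: the RDI
        interaction, only defined for the +RDI variant).

    The per-edge t is the effect-of-interest coefficient over its standard
    error, with a two-sided p from the t distribution at the residual
    degrees of freedom; the VIF of the effect of interest is also reported.
    """
    z = np.asarray(z, dtype=float)
    n, n_edges = z.shape
    if n != pheno.n_subjects:
        raise ValueError("z rows must match phenotype rows")
    if len(pairs) != n_edges:
        raise ValueError("pairs must match z columns")

    include_group = "-GRP" not in model
    has_rdi = "RDI" in model
    if include_group:
        interest = "grp"
    elif has_rdi:
        interest = "drd_ab"
    else:
        raise ValueError("STD-GRP has no effect of interest; use ftest_rdi")

    X0, labels0 = _std_design(pheno, include_group)
    p_std = X0.shape[1]

    if not has_rdi:
        # shared design: one decomposition serves every edge
        labels = labels0
        dof = n - p_std
        if dof <= 0:
            raise ValueError("more parameters than subjects")
        if np.linalg.matrix_rank(X0) < p_std:
            raise ValueError(_collinear_message(X0, labels0))
        XtX_inv = np.linalg.pinv(X0.T @ X0)
        B = XtX_inv @ X0.T @ z                      # (p, n_edges)
        resid = z - X0 @ B
        rss = (resid ** 2).sum(axis=0)
        j = labels.index(interest)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * XtX_inv[j, j])
        coefs = B.T
        tval = np.divide(coefs[:, j], se, out=np.zeros(n_edges), where=se > 0)
        vif = vif_of_interest(X0, j)
        vifs = np.full(n_edges, vif)
    else:
        labels = labels0 + RDI_COLUMNS
        coefs = np.empty((n_edges, len(labels)))
        rss = np.empty(n_edges)
        se = np.empty(n_edges)
        vifs = np.empty(n_edges)
        dof = n - len(labels)
        if dof <= 0:
            raise ValueError("more parameters than subjects")
        j = labels.index(interest)
        for e, pair in enumerate(pairs):
            X, _ = build_design_matrix(pheno, model, pair)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(_collinear_message(X, labels))
            b, r, XtX_inv = _ols_fit(X, z[:, e])
            coefs[e] = b
            rss[e] = r
            se[e] = np.sqrt(r / dof * XtX_inv[j, j])
            vifs[e] = vif_of_interest(X, j)
        tval = np.divide(coefs[:, j], se, out=np.zeros(n_edges), where=se > 0)

    degenerate = _is_degenerate(rss, z)
    if np.any(degenerate):
        warnings.warn(f"{int(degenerate.sum())} edge(s) with zero residual sum "
                      "of squares (exact interpolation); p set to 0")
    pval = 2 * stats.t.sf(np.abs(tval), dof)
    pval[degenerate] = 0.0

    table = pd.DataFrame(
        {
            "region_a": [a for a, _ in pairs],
            "region_b": [b for _, b in pairs],
            "beta": coefs[:, j],
            "se": se,
            "t": tval,
            "p": pval,
            "rss": rss,
            "dof": dof,
            "vif": vifs,
            "degenerate": degenerate,
        }
    )
    return EdgeModelResult(model, table, coefs, labels, interest)


def _is_degenerate(rss: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Exact-interpolation flag: RSS negligible relative to the response."""
    tss = ((z - z.mean(axis=0)) ** 2).sum(axis=0)
    return rss <= 1e-12 * np.maximum(tss, 1e-30)


def _collinear_message(X: np.ndarray, labels: list[str]) -> str:
    """Name (a superset of) the collinear columns for the error message."""
    bad = []
    kept: list[int] = []
    for jj in range(X.shape[1]):
        cand = X[:, kept + [jj]]
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            bad.append(labels[jj])
        else:
            kept.append(jj)
    return f"rank-deficient design; collinear columns: {bad}"


def ftest_rdi(
    z: np.ndarray,
    pairs: list[tuple[int, int]],
    pheno: PhenotypeTable,
    include_group: bool = False,
) -> pd.DataFrame:
    """Nested F-test of the three RDI terms, per edge.

    Compares the reduced model (STD covariates, group excluded by default as
    in the characterization analysis on a single population) against the
    RDI-augmented model on identical subject rows:

        F = ((RSS_red - RSS_full) / 3) / (RSS_full / (n - p_full))

    with p from the F(3, n - p_full) distribution.  Edges where the full
    model interpolates exactly (RSS_full = 0) are flagged and given p = 0.
    """
    suffix = "" if include_group else "-GRP"
    red = fit_edge_glm(z, pairs, pheno, "STD" + suffix) if include_group else \
        _fit_nogrp(z, pairs, pheno, rdi=False)
    full = fit_edge_glm(z, pairs, pheno, "STD+RDI" + suffix) if include_group else \
        _fit_nogrp(z, pairs, pheno, rdi=True)
    rss_red = red.table["rss"].to_numpy() if include_group else red["rss"]
    rss_full = full.table["rss"].to_numpy() if include_group else full["rss"]
    dof_full = (full.table["dof"].iloc[0] if include_group else full["dof"])

    df_num = 3
    degenerate = _is_degenerate(np.asarray(rss_full), z)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss_red - rss_full) / df_num) / (rss_full / dof_full)
    F = np.where(degenerate, np.inf, np.maximum(F, 0.0))
    p = stats.f.sf(F, df_num, dof_full)
    p = np.where(degenerate, 0.0, p)
    if degenerate.any():
        warnings.warn("zero-RSS full model for some edges; F-test degenerate")
    return pd.DataFrame(
        {
            "region_a": [a for a, _ in pairs],
            "region_b": [b for _, b in pairs],
            "F": F,
            "p": p,
            "dof_num": df_num,
            "dof_den": dof_full,
            "degenerate": degenerate,
        }
    )


def _fit_nogrp(z, pairs, pheno, rdi: bool) -> dict:
    """RSS of the group-excluded models (reduced/full) for the F-test."""
    n, n_edges = z.shape
    X0, _ = _std_design(pheno, include_group=False)
    rss = np.empty(n_edges)
    if not rdi:
        XtX_inv = np.linalg.pinv(X0.T @ X0)
        B = XtX_inv @ X0.T @ z
        rss = ((z - X0 @ B) ** 2).sum(axis=0)
        dof = n - X0.shape[1]
    else:
        dof = n - (X0.shape[1] + 3)
        for e, (a, b) in enumerate(pairs):
            da = pheno.delta_rd[:, a]
            db = pheno.delta_rd[:, b]
            X = np.column_stack([X0, da, db, da * db])
            _, r, _ = _ols_fit(X, z[:, e])
            rss[e] = r
    return {"rss": rss, "dof": dof}


def pooled_rdi_model(
    z: np.ndarray,
    pairs: list[tuple[int, int]],
    pheno: PhenotypeTable,
    row_cap: int = 2_000_000,
    surface_grid: int = 21,
):
    """One model for all connections of all subjects (pooled RDI fit).

    The dependent variable and covariates of every edge are concatenated
    into a single design with n_subjects * n_edges rows; the effect of
    interest is the RDI interaction term.  Returns a dict with the fitted
    statsmodels result, the interaction t and p, and a predicted-Z surface
    over a dRD_A x dRD_B lattice with the other covariates held at their
    means (the contour-plot analogue used to visualise the interaction).

    Within-subject dependence between edges is ignored by construction;
    interpret the pooled p-value accordingly.
    """
    import statsmodels.api as sm

    z = np.asarray(z, float)
    n, n_edges = z.shape
    if n * n_edges > row_cap:
        raise MemoryError(
            f"pooled design would have {n * n_edges} rows (> cap {row_cap}); "
            "subsample edges or raise row_cap"
        )
    X0, labels0 = _std_design(pheno, include_group=False)
    rows_X = []
    rows_y = []
    for e, (a, b) in enumerate(pairs):
        da = pheno.delta_rd[:, a]
        db = pheno.delta_rd[:, b]
        rows_X.append(np.column_stack([X0, da, db, da * db]))
        rows_y.append(z[:, e])
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    labels = labels0 + RDI_COLUMNS
    res = sm.OLS(y, X).fit()
    jj = labels.index("drd_ab")

    # predicted surface over the dRD lattice at covariate means
    da_all = X[:, labels.index("drd_a")]
    db_all = X[:, labels.index("drd_b")]
    ga = np.linspace(da_all.min(), da_all.max(), surface_grid)
    gb = np.linspace(db_all.min(), db_all.max(), surface_grid)
    AA, BB = np.meshgrid(ga, gb, indexing="ij")
    base = X.mean(axis=0)
    Xg = np.tile(base, (surface_grid * surface_grid, 1))
    Xg[:, labels.index("drd_a")] = AA.ravel()
    Xg[:, labels.index("drd_b")] = BB.ravel()
    Xg[:, jj] = AA.ravel() * BB.ravel()
    surface = (Xg @ res.params).reshape(surface_grid, surface_grid)

    return {
        "result": res,
        "columns": labels,
        "t_interaction": float(res.tvalues[jj]),
        "p_interaction": float(res.pvalues[jj]),
        "beta_interaction": float(res.params[jj]),
        "n_rows": int(X.shape[0]),
        "surface_drd_a": ga,
        "surface_drd_b": gb,
        "surface_z": surface,
    }


def vif_of_interest(X: np.ndarray, col: int) -> float:
    """Variance inflation factor of column *col* of a design with intercept.

    VIF = 1 / (1 - R^2) where R^2 comes from regressing the column of
    interest on the remaining non-intercept columns (plus intercept).
    Perfect collinearity is reported as ``inf``.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    is_intercept = [np.allclose(X[:, j], X[0, j]) for j in range(p)]
    others = [j for j in range(p) if j != col and not is_intercept[j]]
    if not others:
        return 1.0
    y = X[:, col]
    Xo = np.column_stack([np.ones(n)] + [X[:, j] for j in others])
    beta, *_ = np.linalg.lstsq(Xo, y, rcond=None)
    resid = y - Xo @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return np.inf
    r2 = 1.0 - (resid @ resid) / tss
    if r2 >= 1.0 - 1e-12:
        warnings.warn("perfect collinearity with the effect of interest")
        return np.inf
    return float(1.0 / (1.0 - r2))


def fdr_control(p: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and a (q < level) mask."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals < q


def build_spn(
    result: EdgeModelResult | pd.DataFrame,
    rule: str = "p",
    alpha: float = 0.01,
) -> SPN:
    """Threshold per-edge statistics into an SPN.

    ``rule="p"`` keeps edges with p < alpha; ``rule="q"`` applies BH FDR at
    level alpha and keeps edges with q < alpha.  The edge sign (direction of
    the group difference) is carried along when a t statistic is present.
    """
    table = result.table if isinstance(result, EdgeModelResult) else result
    table = table.copy()
    if rule == "q":
        qvals, mask = fdr_control(table["p"].to_numpy(), alpha)
        table["q"] = qvals
        kept = table[mask]
        desc = f"q<{alpha}"
    elif rule == "p":
        kept = table[table["p"] < alpha]
        desc = f"p<{alpha}"
    else:
        raise ValueError("rule must be 'p' or 'q'")
    if "t" in kept.columns:
        kept = kept.assign(sign=np.sign(kept["t"]))
    return SPN(kept.reset_index(drop=True), desc, len(table))
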