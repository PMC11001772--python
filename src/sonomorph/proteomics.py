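"""Differential-expression statistics for two-group protein abundance tables.

The modelling surface follows the statsmodels idiom: build a
:class:`DifferentialExpression` model from an :class:`AbundanceTable`, call
``fit()`` and work with the returned :class:`DEResults` (per-protein log2
fold change, Welch t, p, Benjamini–Hochberg q, direction; ``summary()``
prints the counts).  PCA scores and top-k selection with hierarchical
ordering are provided alongside.

Statistical model: per protein, a two-sample comparison of log2 abundances
between the 'patterned' and 'random' groups.  The default test is the
pooled equal-variance t (df = n1 + n2 - 2): at n = 3 per group the
Welch–Satterthwaite degrees of freedom collapse toward 2 whenever the two
tiny variance estimates disagree, costing ~8% sensitivity even when the
true variances are equal, and the pooled test is also what the common
proteomics front-ends apply by default.  Welch's unequal-variance t is
available via ``equal_var=False``.  Multiplicity is controlled by
Benjamini–Hochberg FDR across all proteins; a protein is called up (down)
when q < alpha and log2FC is positive (negative), with an optional absolute
fold-change cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, DomainError

__all__ = [
    "AbundanceTable",
    "normalize",
    "DifferentialExpression",
    "DEResults",
    "PCAScores",
    "pca_scores",
    "top_k",
    "TopKResult",
]

GROUPS = ("patterned", "random")


class AbundanceTable:
    """Proteins x samples abundance matrix with group labels.

    Parameters
    ----------
    data : DataFrame
        Rows = proteins (unique ids), columns = samples; strictly positive
        raw abundances unless ``is_log2`` is set.
    groups : mapping sample -> {'patterned', 'random'}
        Every column must be labelled; each group needs >= 2 samples.
    is_log2 : bool
        Whether ``data`` is already on the log2 scale.
    """

    def __init__(self, data: pd.DataFrame, groups: Mapping[str, str],
                 is_log2: bool = False) -> None:
        if data.index.has_duplicates:
            raise ConfigError("duplicate protein identifiers")
        missing = [c for c in data.columns if c not in groups]
        if missing:
            raise ConfigError(f"samples without group label: {missing}")
        bad = {g for g in groups.values()} - set(GROUPS)
        if bad:
            raise ConfigError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if sum(1 for c in data.columns if groups[c] == g) < 2:
                raise ConfigError(f"group {g!r} needs at least 2 samples")
        if not is_log2 and not (data.to_numpy() > 0).all():
            raise DomainError("abundances must be strictly positive")
        self.data = data
        self.groups = dict(groups)
        self.is_log2 = is_log2
        self.provenance: list[str] = []

    # -- convenience -------------------------------------------------------
    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]

    def log2_values(self) -> pd.DataFrame:
        return self.data if self.is_log2 else np.log2(self.data)

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_files(cls, table_path, groups_path, sep="\t") -> "AbundanceTable":
        """Read a proteins-x-samples table and a two-column sample/group map."""
        data = pd.read_csv(table_path, sep=sep, index_col=0)
        gmap = pd.read_csv(groups_path, sep=sep)
        groups = dict(zip(gmap.iloc[:, 0].astype(str), gmap.iloc[:, 1].astype(str)))
        return cls(data, groups)

    def to_files(self, table_path, groups_path, sep="\t") -> None:
        self.data.to_csv(table_path, sep=sep)
        pd.DataFrame({"sample": list(self.data.columns),
                      "group": [self.groups[c] for c in self.data.columns]}
                     ).to_csv(groups_path, sep=sep, index=False)


def normalize(table: AbundanceTable, mode: str = "log2_median_center") -> AbundanceTable:
    """Return a normalized copy of the table.

    Modes: ``log2`` (log2 transform only), ``log2_median_center`` (log2 then
    per-sample median centering), ``autoscale`` (log2, then per-protein mean
    0 / SD 1).
    """
    if mode not in ("log2", "log2_median_center", "autoscale"):
        raise ConfigError(f"unknown normalization mode {mode!r}")
    x = table.log2_values().copy()
    if mode in ("log2_median_center",):
        x = x - x.median(axis=0)
    elif mode == "autoscale":
        sd = x.std(axis=1, ddof=1).replace(0.0, 1.0)
        x = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)
    out = AbundanceTable(x, table.groups, is_log2=True)
    out.provenance = table.provenance + [f"normalize:{mode}"]
    return out


@dataclass
class DEResults:
    """Per-protein differential-expression results.

    ``frame`` columns: log2fc (patterned - random), t, p, q, direction
    ('up' / 'down' / 'ns').
    """

    frame: pd.DataFrame
    alpha: float
    lfc_cutoff: float
    equal_var: bool
    n_flagged_zero_variance: int = 0

    @property
    def counts(self) -> dict[str, int]:
        vc = self.frame["direction"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Differential expression (pooled t, BH-FDR)"
            if self.equal_var else "Differential expression (Welch t, BH-FDR)",
            f"  proteins tested : {len(self.frame)}",
            f"  alpha (q)       : {self.alpha}",
            f"  |log2FC| cutoff : {self.lfc_cutoff}",
            f"  up-regulated    : {c['up']}",
            f"  down-regulated  : {c['down']}",
            f"  not significant : {c['ns']}",
        ]
        if self.n_flagged_zero_variance:
            lines.append(f"  zero-variance p=1 flags: {self.n_flagged_zero_variance}")
        return "\n".join(lines)


class DifferentialExpression:
    """Two-group differential-expression model on an abundance table."""

    def __init__(self, table: AbundanceTable) -> None:
        self.table = table

    def fit(self, alpha: float = 0.05, lfc_cutoff: float = 0.0,
            equal_var: bool = True) -> DEResults:
        """Per-protein two-sample t-tests with BH adjustment.

        Pooled equal-variance t by default (``equal_var=False`` selects
        Welch's test; see the module docstring for why pooled is the default
        at n = 3).  A protein with zero variance in both groups and equal
        means is assigned p = 1 by convention and counted in the results'
        ``n_flagged_zero_variance``.
        """
        x = self.table.log2_values()
        a = x[self.table.group_columns("patterned")].to_numpy(dtype=float)
        b = x[self.table.group_columns("random")].to_numpy(dtype=float)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
        degenerate = ~np.isfinite(p)
        n_flagged = int(degenerate.sum())
        if n_flagged:
            warnings.warn(f"{n_flagged} proteins with zero variance in both "
                          "groups; p set to 1", stacklevel=2)
            t = np.where(degenerate, 0.0, t)
            p = np.where(degenerate, 1.0, p)
        q = multipletests(p, method="fdr_bh")[1]
        sig = (q < alpha) & (np.abs(lfc) >= lfc_cutoff)
        direction = np.where(sig & (lfc > 0), "up",
                             np.where(sig & (lfc < 0), "down", "ns"))
        frame = pd.DataFrame(
            {"log2fc": lfc, "t": t, "p": p, "q": q, "direction": direction},
            index=x.index)
        return DEResults(frame=frame, alpha=alpha, lfc_cutoff=lfc_cutoff,
                         equal_var=equal_var, n_flagged_zero_variance=n_flagged)


def differential_expression(table: AbundanceTable, alpha: float = 0.05,
                            **kwargs) -> DEResults:
    """Functional shorthand for ``DifferentialExpression(table).fit(alpha)``."""
    return DifferentialExpression(table).fit(alpha=alpha, **kwargs)


@dataclass
class PCAScores:
    """Sample scores and explained-variance fractions of a PCA."""

    scores: pd.DataFrame  # samples x components
    explained: np.ndarray  # variance fractions, non-increasing
    loadings: pd.DataFrame = dc_field(repr=False, default=None)


def pca_scores(table: AbundanceTable, n_components: int = 2) -> PCAScores:
    """PCA of samples in protein space (log2 scale, protein-centered).

    Scores come from the SVD of the centered samples x proteins matrix
    (equivalent to eigen-decomposition of the sample covariance); the sign
    convention makes the largest-magnitude loading of each component
    positive.  Score columns are centered by construction.
    """
    x = table.log2_values().to_numpy(dtype=float).T  # samples x proteins
    if x.shape[1] < 2:
        raise ConfigError("PCA needs at least 2 proteins")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    load = vt[:k].T
    for j in range(k):  # deterministic sign convention
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    denom = (s ** 2).sum()
    explained = (s[:k] ** 2) / denom if denom > 0 else np.zeros(k)
    cols = [f"PC{j+1}" for j in range(k)]
    return PCAScores(
        scores=pd.DataFrame(scores, index=table.data.columns, columns=cols),
        explained=explained,
        loadings=pd.DataFrame(load, index=table.data.index, columns=cols))


@dataclass
class TopKResult:
    """The k most significant proteins with dendrogram orderings."""

    ids: list[str]
    data: pd.DataFrame  # autoscaled log2 values, rows = selected proteins
    row_order: list[str]
    col_order: list[str]


def top_k(de: DEResults, table: AbundanceTable, k: int = 50) -> TopKResult:
    """Select the k smallest-q proteins (ties: larger |log2FC| first) and
    order rows/columns by average-linkage hierarchical clustering on
    Euclidean distances of autoscaled log2 values."""
    sig = de.frame[de.frame["direction"] != "ns"]
    if len(sig) < k:
        warnings.warn(f"only {len(sig)} significant proteins; truncating k={k}",
                      stacklevel=2)
        k = len(sig)
    order = sig.sort_values(["q", "log2fc"],
                            key=lambda s: s if s.name == "q" else -s.abs())
    ids = list(order.index[:k])
    x = table.log2_values().loc[ids]
    sd = x.std(axis=1, ddof=1).replace(0.0, 1.0)
    z = x.sub(x.mean(axis=1), axis=0).div(sd, axis=0)

    def _leaf_order(mat: np.ndarray, labels) -> list:
        if len(labels) < 3:
            return list(labels)
        link = hierarchy.linkage(mat, method="average", metric="euclidean")
        return [labels[i] for i in hierarchy.leaves_list(link)]

    row_order = _leaf_order(z.to_numpy(), list(z.index))
    col_order = _leaf_order(z.to_numpy().T, list(z.columns))
    return TopKResult(ids=ids, data=z, row_order=row_order, col_order=col_order)
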