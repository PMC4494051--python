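"""Statistics used by the extension survey.

The headline analyses are a G-test of independence on mutation-class
contingency tables (point stop-loss vs frameshift counts compared across
studies), geometric means with back-transformed 95% confidence intervals for
the added/new/readthrough length distributions, a two-tailed t-test on
log-transformed lengths, and a monophyly check of addition-allele carriers
on the strain tree.

Length distributions of C-terminal extensions are strongly right-skewed and
approximately lognormal, hence all location statistics are computed on the
natural-log scale and back-transformed for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import StrainTree
from .model import CatalogRow


@dataclass
class GTestResult:
    g: float
    df: int
    p_value: float


@dataclass
class LogScaleSummary:
    n: int
    geometric_mean: float
    lower: float
    upper: float


def g_test(table, williams_correction: bool = False) -> GTestResult:
    """Log-likelihood-ratio (G) test of independence on a contingency table.

    G = 2 * sum O * ln(O/E) with expectations from the row/column margins
    (cells with O = 0 contribute nothing), referred to a chi-square with
    (r-1)(c-1) degrees of freedom. No correction is applied by default;
    ``williams_correction=True`` divides G by the Williams factor.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D nonnegative array")
    if not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain integer counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("all row and column margins must be positive")
    expected = np.outer(row, col) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = 2.0 * terms.sum()
    if williams_correction:
        r, c = obs.shape
        q = 1.0 + ((total / row).sum() - 1.0) * ((total / col).sum() - 1.0) / (
            6.0 * total * (r - 1) * (c - 1)
        )
        g /= q
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(g=float(g), df=df, p_value=float(sps.chi2.sf(g, df)))


def geometric_mean_ci(values, alpha: float = 0.05) -> LogScaleSummary:
    """Geometric mean with a back-transformed t-based confidence interval.

    gm = exp(mean(ln x)); the CI is exp(mean +/- t_{n-1,1-alpha/2} * s/sqrt(n))
    computed on the logs. All values must be positive.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if (x <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    logs = np.log(x)
    m = logs.mean()
    if x.size >= 2:
        half = sps.t.ppf(1 - alpha / 2, x.size - 1) * logs.std(ddof=1) / np.sqrt(x.size)
    else:
        half = 0.0
    return LogScaleSummary(
        n=int(x.size),
        geometric_mean=float(np.exp(m)),
        lower=float(np.exp(m - half)),
        upper=float(np.exp(m + half)),
    )


def log_t_test(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample two-tailed t-test on ln-transformed values.

    Pooled-variance Student form by default; ``welch=True`` drops the
    equal-variance assumption. Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need n >= 2")
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("log transform requires positive values")
    lx, ly = np.log(x), np.log(y)
    res = sps.ttest_ind(lx, ly, equal_var=not welch)
    if welch:
        vx, vy = lx.var(ddof=1) / lx.size, ly.var(ddof=1) / ly.size
        df = (vx + vy) ** 2 / (vx**2 / (lx.size - 1) + vy**2 / (ly.size - 1))
    else:
        df = lx.size + ly.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def is_monophyletic(tree: StrainTree, strain_set) -> bool:
    """True iff ``strain_set`` is one side of some bipartition of the tree.

    The tree is interpreted as unrooted: each edge splits the leaves into two
    parts, and the query (or its complement) must equal one part exactly.
    The trivial splits (a single leaf, or all leaves) are monophyletic.
    """
    query = frozenset(strain_set)
    leaves = frozenset(tree.leaf_labels)
    unknown = query - leaves
    if unknown:
        raise KeyError(f"strains not in tree: {sorted(unknown)}")
    if not query or query == leaves or len(query) == 1:
        return bool(query)
    dt = tree.tree
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if clade == query or leaves - clade == query:
            return True
    return False


def summarize_catalog(rows: list[CatalogRow], reference_ratios=((19, 20), (5, 50))) -> dict:
    """Summary statistics over a catalog of addition events.

    Counts by mutation class and species, added/new extremes, geometric means
    over the non-fusion rows, and G-tests of the point:frameshift ratio
    against the supplied reference ratios (defaults: the fixed yeast
    interspecies 19:20 ratio and the mouse:rat 5:50 ratio).
    """
    summary: dict = {
        "n_rows": len(rows),
        "by_class": {c: 0 for c in ("point", "frameshift", "deletion_fusion")},
        "by_species": {},
    }
    for r in rows:
        summary["by_class"][r.mutation_class] += 1
        summary["by_species"][r.species] = summary["by_species"].get(r.species, 0) + 1
    nonfusion = [r for r in rows if r.mutation_class != "deletion_fusion"]
    if nonfusion:
        added = [r.added_aa for r in nonfusion]
        new = [r.new_aa for r in nonfusion]
        summary.update(
            min_added=min(added), max_added=max(added),
            min_new=min(new), max_new=max(new),
        )
        if all(a > 0 for a in added):
            gm = geometric_mean_ci(added)
            summary["added_geometric_mean"] = gm.geometric_mean
            summary["added_gm_ci"] = (gm.lower, gm.upper)
        if all(v > 0 for v in new):
            summary["new_geometric_mean"] = geometric_mean_ci(new).geometric_mean
    else:
        summary.update(min_added=0, max_added=0, min_new=0, max_new=0)
    n_point = summary["by_class"]["point"]
    n_fs = summary["by_class"]["frameshift"]
    summary["point_frameshift_ratio"] = (n_point, n_fs)
    summary["ratio_tests"] = {}
    if n_point + n_fs > 0:
        for ref in reference_ratios:
            try:
                res = g_test([[n_point, n_fs], list(ref)])
            except ValueError:
                continue
            summary["ratio_tests"][f"{ref[0]}:{ref[1]}"] = {
                "G": res.g, "df": res.df, "p": res.p_value,
            }
    return summary
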