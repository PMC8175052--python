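"""Downstream statistics: quadratic regressions, GC-bin slopes, contrasts.

Three analyses sit on top of the centile table.  (1) Per mutation category,
diversity is regressed on GC content and coding (CDS) density with linear,
quadratic and interaction terms, then reduced stepwise until only
significant terms remain.  (2) Because GC and CDS density are themselves
correlated, centiles are also cut into equidistant GC bins and the
pi-on-CDS slope is estimated within each bin, holding the GC range roughly
constant.  (3) Among-population comparisons of traits (e.g. B against pi or
chromosome number) use Felsenstein's phylogenetically independent
contrasts, regressed through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

_FULL_TERMS = ("gc", "I(gc ** 2)", "cds", "I(cds ** 2)", "gc:cds")
#: drop priority on p-value ties: higher-order terms go first
_TERM_ORDER = {"gc": 0, "cds": 0, "I(gc ** 2)": 1, "I(cds ** 2)": 1, "gc:cds": 2}


@dataclass
class RegressionReport:
    terms: list[str]
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    dropped: list[str] = field(default_factory=list)


def quadratic_model_reduce(data: pd.DataFrame, response: str = "pi",
                           alpha: float = 0.05) -> RegressionReport:
    """Fit pi ~ gc + gc^2 + cds + cds^2 + gc:cds and reduce stepwise.

    ``data`` needs columns ``gc``, ``cds`` and the response.  At each step
    the least significant term with p >= alpha is dropped (ties broken by
    dropping the higher-order term) and the model refitted, until every
    retained term is significant.  The intercept is never dropped.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 observations")
    terms = list(_FULL_TERMS)
    dropped: list[str] = []
    while True:
        formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
        res = smf.ols(formula, data=data).fit()
        pvals = res.pvalues.drop("Intercept", errors="ignore")
        insig = pvals[pvals >= alpha]
        if insig.empty or not terms:
            break
        worst_p = insig.max()
        ties = [t for t in insig.index if np.isclose(insig[t], worst_p, rtol=0, atol=1e-12)]
        victim = max(ties, key=lambda t: (_TERM_ORDER.get(t, 0), t))
        terms.remove(victim)
        dropped.append(victim)
    return RegressionReport(terms=terms, params=res.params, tvalues=res.tvalues,
                            pvalues=res.pvalues, rsquared=res.rsquared, dropped=dropped)


def gc_bin_slopes(centile_table: pd.DataFrame, n_bins: int = 5,
                  categories: tuple[str, ...] = ("SS", "WW", "SW", "WS")
                  ) -> pd.DataFrame:
    """Within equidistant GC bins, regress per-category pi on CDS density.

    Bin edges partition [min gc, max gc] exactly.  Each row is one
    (bin, category) slope with R^2 and p, plus the within-bin slope of
    cds_density on gc (category "cds~gc").  The last bin is flagged, as are
    bins with fewer than 3 centiles, and should not enter cross-bin trend
    statements.
    """
    gc = centile_table["gc"].to_numpy()
    edges = np.linspace(gc.min(), gc.max(), n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, gc, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sub = centile_table[bin_idx == b]
        flagged = (b == n_bins - 1) or (len(sub) < 3)
        pairs = [(f"pi_{cat}", "cds_density", cat) for cat in categories]
        pairs.append(("cds_density", "gc", "cds~gc"))
        for ycol, xcol, label in pairs:
            if len(sub) >= 3 and ycol in sub:
                X = sm.add_constant(sub[xcol].to_numpy())
                res = sm.OLS(sub[ycol].to_numpy(), X).fit()
                k, p, r2 = res.params[1], res.pvalues[1], res.rsquared
            else:
                k = p = r2 = np.nan
            rows.append({"bin": b + 1, "gc_lo": edges[b], "gc_hi": edges[b + 1],
                         "n_centiles": len(sub), "category": label,
                         "k": k, "k_x1000": k * 1e3, "r2": r2, "p": p,
                         "flagged": flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phylogenetically independent contrasts


def _as_tree(tree):
    import dendropy

    if isinstance(tree, str):
        return dendropy.Tree.get(data=tree, schema="newick")
    return tree


def independent_contrasts(tree, tip_values: dict[str, float],
                          default_branch_length: float = 1.0) -> pd.DataFrame:
    """Felsenstein contrasts on a rooted binary tree.

    At each internal node the standardized contrast is
    (x_left - x_right)/sqrt(v_left + v_right); the node's value is the
    branch-length-weighted average of its children and its own branch is
    augmented by v_l*v_r/(v_l+v_r).  Missing branch lengths default to
    ``default_branch_length``.  Polytomies raise.
    """
    tree = _as_tree(tree)
    rows = []

    def visit(node):
        children = node.child_nodes()
        if not children:
            label = node.taxon.label if node.taxon else node.label
            if label not in tip_values:
                raise ValueError(f"no trait value for tip {label!r}")
            bl = node.edge.length if node.edge.length is not None else default_branch_length
            return float(tip_values[label]), float(bl)
        if len(children) != 2:
            raise ValueError("polytomy encountered; resolve the tree upstream")
        (x_l, v_l), (x_r, v_r) = visit(children[0]), visit(children[1])
        contrast = (x_l - x_r) / np.sqrt(v_l + v_r)
        rows.append({"node": len(rows), "contrast": contrast, "variance": v_l + v_r})
        x = (x_l / v_l + x_r / v_r) / (1.0 / v_l + 1.0 / v_r)
        bl = node.edge.length if node.edge.length is not None else default_branch_length
        if node.parent_node is None:
            bl = 0.0
        return x, bl + v_l * v_r / (v_l + v_r)

    visit(tree.seed_node)
    return pd.DataFrame(rows)


def contrast_regression(contrasts_x, contrasts_y) -> dict:
    """Regression through the origin of y-contrasts on x-contrasts."""
    x = np.asarray(contrasts_x, dtype=float)
    y = np.asarray(contrasts_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("contrast vectors must have equal length")
    res = sm.OLS(y, x[:, None]).fit()
    return {"slope": float(res.params[0]), "p": float(res.pvalues[0]),
            "r2": float(res.rsquared), "df": int(res.df_resid)}


def range_midpoint(value) -> float:
    """Midpoint of a 'lo-hi' trait range string (e.g. chromosome numbers);
    plain numbers pass through."""
    if isinstance(value, str) and "-" in value.strip("-"):
        lo, hi = value.split("-", 1)
        return (float(lo) + float(hi)) / 2.0
    return float(value)
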