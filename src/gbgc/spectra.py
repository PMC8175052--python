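"""Derived-allele-frequency spectra per mutation category.

Polarized SNPs are binned by derived-allele count i (1..n-1) separately for
the four mutation categories defined by the strong (S = G/C) and weak
(W = A/T) base classes: S->S, W->W (GC-conservative, jointly "N->N") and the
GC-changing S->W and W->S. Per-category nucleotide diversity is normalized
by the mutational opportunity L_X, the number of unmasked ancestral bases of
the originating class X. The module also provides the folded-SFS skew
diagnostic whose sign gives the direction of GC-content evolution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("SS", "WW", "SW", "WS")

#: categories normalized by the strong-base opportunity L_S
_S_ORIGIN = ("SS", "SW")
#: categories normalized by the weak-base opportunity L_W
_W_ORIGIN = ("WW", "WS")


@dataclass
class CategorySpectra:
    """Per-category DAF spectra at fixed haploid sample size ``n``.

    ``counts[cat][i-1]`` is the number of polarized sites of category
    ``cat`` with derived-allele count ``i``.  ``L_W`` and ``L_S`` are the
    unmasked ancestral A/T and G/C base counts of the summarized region.
    """

    n: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    L_W: float = 0.0
    L_S: float = 0.0

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            arr = np.asarray(self.counts.get(cat, np.zeros(self.n - 1)), dtype=float)
            if arr.shape != (self.n - 1,):
                raise ValueError(f"spectrum for {cat} must have length n-1={self.n - 1}")
            if (arr < 0).any():
                raise ValueError("spectrum counts must be non-negative")
            self.counts[cat] = arr

    @property
    def nn(self) -> np.ndarray:
        """GC-conservative spectrum, S->S and W->W merged."""
        return self.counts["SS"] + self.counts["WW"]

    def total(self, cat: str) -> float:
        return float(self.counts[cat].sum())

    def opportunity(self, cat: str) -> float:
        """Mutational opportunity L_X of the ancestral class of ``cat``."""
        return self.L_S if cat in _S_ORIGIN else self.L_W

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#n={self.n}\tL_W={self.L_W!r}\tL_S={self.L_S!r}\n")
            fh.write("category\ti\tcount\n")
            for cat in CATEGORIES:
                for i in range(1, self.n):
                    fh.write(f"{cat}\t{i}\t{self.counts[cat][i - 1]:.10g}\n")

    @classmethod
    def from_tsv(cls, path) -> "CategorySpectra":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("spectrum TSV must start with a '#n=...' header line")
            meta = dict(kv.split("=", 1) for kv in header[1:].split())
            body = fh.read()
        n = int(meta["n"])
        df = pd.read_csv(io.StringIO(body), sep="\t")
        counts = {cat: np.zeros(n - 1) for cat in CATEGORIES}
        for _, row in df.iterrows():
            counts[row["category"]][int(row["i"]) - 1] = row["count"]
        return cls(n=n, counts=counts, L_W=float(meta["L_W"]), L_S=float(meta["L_S"]))


def build_spectra(sites, n: int, L_W: float, L_S: float) -> CategorySpectra:
    """Histogram polarized sites into per-category DAF spectra.

    ``sites`` is an iterable of objects (or a DataFrame) with ``category``
    and ``derived_count`` (alias ``i``) attributes.  Sites must share the
    haploid sample size ``n``; a derived count outside [1, n-1] indicates an
    upstream polarization bug and raises.
    """
    counts = {cat: np.zeros(n - 1) for cat in CATEGORIES}
    if isinstance(sites, pd.DataFrame):
        icol = "derived_count" if "derived_count" in sites.columns else "i"
        it: Iterable = zip(sites["category"], sites[icol])
    else:
        it = ((s.category, s.derived_count) for s in sites)
    for cat, i in it:
        i = int(i)
        if not 1 <= i <= n - 1:
            raise ValueError(f"derived count {i} outside [1, {n - 1}]")
        counts[cat][i - 1] += 1
    return CategorySpectra(n=n, counts=counts, L_W=L_W, L_S=L_S)


def pi_category(x: np.ndarray, n: int, L_X: float) -> float:
    """Per-site diversity of one category: sum_i i(n-i) x_i / (C(n,2) L_X)."""
    if L_X <= 0:
        raise ValueError("mutational opportunity L_X must be positive")
    x = np.asarray(x, dtype=float)
    i = np.arange(1, n)
    return float((i * (n - i) * x).sum() / (n * (n - 1) / 2.0) / L_X)


def pi_spectra(spectra: CategorySpectra) -> dict[str, float]:
    """Per-category and overall per-site diversity from a CategorySpectra."""
    out = {}
    for cat in CATEGORIES:
        L = spectra.opportunity(cat)
        out[cat] = pi_category(spectra.counts[cat], spectra.n, L) if L > 0 else np.nan
    i = np.arange(1, spectra.n)
    num = sum((i * (spectra.n - i) * spectra.counts[cat]).sum() for cat in CATEGORIES)
    out["all"] = float(num / (spectra.n * (spectra.n - 1) / 2.0) / (spectra.L_W + spectra.L_S))
    return out


def pi_all_sites(genotype_matrix: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Average pairwise diversity over a region from 0/1 haplotype calls.

    ``genotype_matrix`` has one row per position (monomorphic rows allowed)
    and one column per haploid genome.  Masked positions are excluded from
    both numerator and denominator.
    """
    g = np.asarray(genotype_matrix)
    if mask is not None:
        g = g[~np.asarray(mask, dtype=bool)]
    if g.shape[0] == 0:
        return 0.0
    n = g.shape[1]
    i = g.sum(axis=1)
    per_site = 2.0 * i * (n - i) / (n * (n - 1))
    return float(per_site.mean())


@dataclass
class SkewEstimate:
    """Signed imbalance of the relative W->S and S->W fixation fluxes.

    Positive means GC content is increasing, negative decreasing; exactly
    zero when GC sits at the gBGC-adjusted equilibrium 1/(1 + lambda e^-B).
    """

    value: float
    ws_flux: float
    sw_flux: float


def _sigma(B: float) -> float:
    """Fixation-rate scaling B / (1 - e^-B), with the neutral limit 1 at B=0."""
    if abs(B) < 1e-8:
        return 1.0 + B / 2.0 + B * B / 12.0
    return B / -np.expm1(-B)


def skew_statistic(B: float, lam: float, gc: float) -> SkewEstimate:
    """Direction-of-GC-evolution diagnostic from fitted (B, lambda) and GC.

    The W->S substitution flux is proportional to the weak-base fraction
    (1-gc) times the gBGC-boosted fixation rate sigma(B); the S->W flux to
    gc * lambda * sigma(-B).  The statistic is their normalized difference,
    in [-1, 1].
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    ws = (1.0 - gc) * _sigma(B)
    sw = gc * lam * _sigma(-B)
    return SkewEstimate(value=(ws - sw) / (ws + sw), ws_flux=ws, sw_flux=sw)
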