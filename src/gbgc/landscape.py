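"""GC landscape: 1 kb ancestral-GC windows and equal-SNP-count centiles.

Local GC content in the masked ancestral genome serves as a proxy for the
long-term recombination environment.  Windows of fixed size (default 1 kb)
are scored for GC over their unmasked bases; polarized SNPs are then ranked
by their window's GC and cut into bins (default 100 "centiles") holding
equal numbers of SNPs, so each centile is an unequally sized chunk of the
genome.  Per centile we aggregate GC, mutational opportunities, coding
density and per-category diversity, and optionally refit the gBGC model
with the centile's GC as the fixed parameter.

A window whose SNPs straddle a centile boundary contributes its bases to
both centiles' GC aggregation: centiles are SNP sets, not genome partitions,
so base double counting across adjacent centiles is accepted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import GBGCModelSpec, fit_model
from .polarize import MaskedAncestralGenome
from .spectra import CATEGORIES, build_spectra, pi_category


def window_gc(genome: MaskedAncestralGenome, window_size: int = 1000) -> pd.DataFrame:
    """Per-window GC corrected for masked/N bases.

    Returns columns chrom, start, end, unmasked, gc_bases, gc, excluded;
    fully masked windows carry gc = NaN and excluded = True.
    """
    rows = []
    for chrom, seq in genome.seqs.items():
        ok = ~genome._counting_mask(chrom)
        strong = ((seq == ord("G")) | (seq == ord("C"))) & ok
        edges = np.arange(0, len(seq), window_size)
        unmasked = np.add.reduceat(ok.astype(np.int64), edges)
        gc_bases = np.add.reduceat(strong.astype(np.int64), edges)
        for k, start in enumerate(edges):
            end = min(start + window_size, len(seq))
            u, g = int(unmasked[k]), int(gc_bases[k])
            rows.append((chrom, int(start), int(end), u, g,
                         g / u if u > 0 else np.nan, u == 0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "unmasked",
                                       "gc_bases", "gc", "excluded"])


def _site_windows(sites: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Index into ``windows`` of the window containing each site."""
    wsize = int((windows["end"] - windows["start"]).max())
    lookup = {(c, s): k for k, (c, s) in enumerate(zip(windows["chrom"], windows["start"]))}
    idx = np.empty(len(sites), dtype=int)
    for j, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        key = (chrom, ((pos - 1) // wsize) * wsize)
        if key not in lookup:
            raise ValueError(f"site {chrom}:{pos} falls in no window")
        k = lookup[key]
        if windows["excluded"].iat[k]:
            raise ValueError(f"site {chrom}:{pos} falls in a fully masked window")
        idx[j] = k
    return idx


def assign_centiles(sites: pd.DataFrame, windows: pd.DataFrame,
                    n_bins: int = 100) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank SNPs by window GC and split into equal-count bins.

    Returns (sites with ``window`` and ``centile`` columns added, centile
    table).  Bin sizes differ by at most one; the remainder goes to the
    lowest ranks.  Ties in window GC are broken by (chrom, pos) so the
    binning is deterministic.
    """
    if len(sites) < n_bins:
        raise ValueError(f"need at least {n_bins} SNPs to form {n_bins} bins")
    sites = sites.copy()
    sites["window"] = _site_windows(sites, windows)
    sites["_wgc"] = windows["gc"].to_numpy()[sites["window"]]
    order = sites.sort_values(["_wgc", "chrom", "pos"], kind="mergesort").index
    base, rem = divmod(len(sites), n_bins)
    sizes = [base + 1 if b < rem else base for b in range(n_bins)]
    centile = np.empty(len(sites), dtype=int)
    k = 0
    for b, size in enumerate(sizes):
        centile[k:k + size] = b + 1
        k += size
    sites.loc[order, "centile"] = centile
    sites["centile"] = sites["centile"].astype(int)
    sites = sites.drop(columns="_wgc")

    recs = []
    for rank, grp in sites.groupby("centile"):
        widx = np.unique(grp["window"].to_numpy())
        w = windows.iloc[widx]
        unmasked = int(w["unmasked"].sum())
        gc_bases = int(w["gc_bases"].sum())
        recs.append({"rank": int(rank), "snp_count": len(grp),
                     "gc": gc_bases / unmasked,
                     "L_S": gc_bases, "L_W": unmasked - gc_bases,
                     "n_windows": len(widx)})
    return sites, pd.DataFrame(recs).sort_values("rank").reset_index(drop=True)


def centile_diversity(sites: pd.DataFrame, centiles: pd.DataFrame,
                      n: int) -> pd.DataFrame:
    """Attach per-category and overall per-site diversity to the centile table.

    Overall diversity counts all polarized SNPs of the centile against its
    total unmasked bases (L_W + L_S).
    """
    out = centiles.copy()
    for cat in CATEGORIES:
        out[f"pi_{cat}"] = 0.0
    out["pi_all"] = 0.0
    pair = n * (n - 1) / 2.0
    for row in out.itertuples():
        grp = sites[sites["centile"] == row.rank]
        total = 0.0
        for cat in CATEGORIES:
            sub = grp[grp["category"] == cat]
            x = np.bincount(sub["i"], minlength=n)[1:n]
            L = row.L_S if cat in ("SS", "SW") else row.L_W
            out.loc[out["rank"] == row.rank, f"pi_{cat}"] = (
                pi_category(x, n, L) if L > 0 else np.nan)
            i = np.arange(1, n)
            total += float((i * (n - i) * x).sum())
        out.loc[out["rank"] == row.rank, "pi_all"] = total / pair / (row.L_W + row.L_S)
    return out


def cds_density(centiles: pd.DataFrame, sites: pd.DataFrame,
                windows: pd.DataFrame, exon_bed: pd.DataFrame) -> pd.DataFrame:
    """Coding fraction of each centile: CDS bases over total bases of its windows."""
    overlap = np.zeros(len(windows))
    by_chrom = {c: g for c, g in exon_bed.groupby("chrom")} if len(exon_bed) else {}
    for k, (chrom, start, end) in enumerate(zip(windows["chrom"], windows["start"],
                                                windows["end"])):
        g = by_chrom.get(chrom)
        if g is None:
            continue
        s = np.maximum(g["start"].to_numpy(), start)
        e = np.minimum(g["end"].to_numpy(), end)
        overlap[k] = np.clip(e - s, 0, None).sum()
    out = centiles.copy()
    dens = []
    for row in out.itertuples():
        widx = np.unique(sites.loc[sites["centile"] == row.rank, "window"].to_numpy())
        w = windows.iloc[widx]
        total = float((w["end"] - w["start"]).sum())
        dens.append(overlap[widx].sum() / total)
    out["cds_density"] = dens
    return out


def fit_centiles(sites: pd.DataFrame, centiles: pd.DataFrame, n: int,
                 model: str = "M1", n_starts: int = 3) -> tuple[pd.DataFrame, dict]:
    """Per-centile model fits with the centile's GC as the fixed parameter.

    Returns the centile table with lambda/B/loglik columns and a summary of
    mean +/- standard error of the mean across centiles.
    """
    out = centiles.copy()
    lams, Bs, lls, conv = [], [], [], []
    for row in out.itertuples():
        grp = sites[sites["centile"] == row.rank]
        sp = build_spectra(grp.rename(columns={"i": "derived_count"}), n,
                           L_W=row.L_W, L_S=row.L_S)
        fit = fit_model(sp, GBGCModelSpec(model, row.gc, n), n_starts=n_starts)
        lams.append(fit.lam)
        Bs.append(fit.B)
        lls.append(fit.loglik)
        conv.append(fit.converged)
    out["lambda"], out["B"], out["loglik"], out["converged"] = lams, Bs, lls, conv
    lam_arr, B_arr = np.asarray(lams), np.asarray(Bs)
    m = len(out)
    summary = {
        "lambda_mean": float(lam_arr.mean()),
        "lambda_sem": float(lam_arr.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
        "B_mean": float(B_arr.mean()),
        "B_sem": float(B_arr.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
    }
    return out, summary


def analyze_landscape(genome: MaskedAncestralGenome, sites: pd.DataFrame,
                      exon_bed: pd.DataFrame | None, n: int,
                      n_bins: int = 100, window_size: int = 1000,
                      fit: bool = False, model: str = "M1") -> tuple[pd.DataFrame, dict]:
    """Windows -> centiles -> diversity (-> per-centile fits) in one call."""
    windows = window_gc(genome, window_size)
    sites, centiles = assign_centiles(sites, windows, n_bins)
    centiles = centile_diversity(sites, centiles, n)
    if exon_bed is not None:
        centiles = cds_density(centiles, sites, windows, exon_bed)
    summary: dict = {}
    if fit:
        centiles, summary = fit_centiles(sites, centiles, n, model=model)
    return centiles, summary
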