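"""Synthetic genomes, variant sets and spectra for end-to-end testing.

The generator emulates the data structure the analysis expects: an
ancestral genome with heterogeneous local GC around 0.32, repeat and exon
masks (coding fraction 3.7% by default), an ingroup of 20 haploid genomes
(ten diploid males) with segregating variants, and outgroup populations
used for polarization.  Site counts per (mutation category, frequency
class) are drawn Poisson from the same expected-spectrum law the inference
assumes — an S->W mutation bias lambda, gBGC of strength B acting on
GC-changing variants, optional demographic distortion r_i — so the
generator's truth is directly comparable to fitted parameters.  Outgroup
divergence enters only as a configurable misorientation fraction: at such
sites the outgroup carries the derived allele and polarization is wrong by
construction.

An optional Wright-Fisher forward mode provides a model-independent check
of the frequency-class weights at small sample size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import likelihood
from .spectra import CategorySpectra

_STRONG = np.frombuffer(b"GC", dtype=np.uint8)
_WEAK = np.frombuffer(b"AT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the system the package targets: genome-wide GC ~ 0.32
    with blockwise local variation, lambda = 3, B ~ 0.2, n = 20 ingroup
    haplotypes, two outgroup populations, 3.7% coding and 10% repeats.
    """

    genome_length: int = 300_000
    n_contigs: int = 3
    window_size: int = 1000
    gc_profile: tuple = ("blockwise", 0.32, 0.05)  # or ("constant", x), ("gradient", lo, hi)
    lam: float = 3.0
    B: float = 0.21
    lam_gradient: tuple[float, float] | None = None  # overrides lam across GC rank
    B_gradient: tuple[float, float] | None = None
    theta_ratio: float = 1.0
    target_snps: int = 10_000
    n_haplotypes: int = 20
    outgroup_sizes: tuple[int, ...] = (2, 2)
    misorientation: float = 0.0
    repeat_fraction: float = 0.10
    exon_fraction: float = 0.037
    r_distortion: tuple[float, ...] | None = None
    n_strata: int = 1
    reference_bias: bool = True  # reference picks the derived allele w.p. i/n

    def __post_init__(self) -> None:
        if not 0.0 <= self.misorientation <= 1.0:
            raise ValueError("misorientation must be in [0, 1]")
        if self.n_haplotypes % 2 or self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be an even number >= 4")
        if self.n_strata < 1:
            raise ValueError("n_strata must be >= 1")


def _window_targets(config: SimulationConfig, n_windows: int, rng) -> np.ndarray:
    kind = config.gc_profile[0]
    if kind == "constant":
        t = np.full(n_windows, config.gc_profile[1])
    elif kind == "gradient":
        lo, hi = config.gc_profile[1:3]
        t = np.linspace(lo, hi, n_windows)
    elif kind == "blockwise":
        mean, sd = config.gc_profile[1:3]
        t = rng.normal(mean, sd, size=n_windows)
    else:
        raise ValueError(f"unknown gc profile {kind!r}")
    return np.clip(t, 0.02, 0.98)


def _random_intervals(length: int, fraction: float, mean_len: int, rng) -> list[tuple[int, int]]:
    covered = np.zeros(length, dtype=bool)
    target = fraction * length
    guard = 0
    while covered.sum() < target and guard < 100_000:
        guard += 1
        ln = max(20, int(rng.exponential(mean_len)))
        s = int(rng.integers(0, max(length - ln, 1)))
        covered[s:s + ln] = True
    # back to merged intervals
    idx = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    return [(int(idx[k]), int(idx[k + 1])) for k in range(0, len(idx), 2)]


def make_genome(config: SimulationConfig, seed: int):
    """Ancestral sequences plus repeat and exon BED frames.

    Per-window GC follows the configured profile in expectation; repeats
    and exons occupy their configured fractions of each contig.
    """
    rng = np.random.default_rng(seed)
    clen = config.genome_length // config.n_contigs
    n_windows_per = -(-clen // config.window_size)
    targets = _window_targets(config, config.n_contigs * n_windows_per, rng)
    seqs: dict[str, np.ndarray] = {}
    rep_rows, ex_rows = [], []
    wk = 0
    for c in range(config.n_contigs):
        name = f"contig_{c + 1}"
        seq = np.empty(clen, dtype=np.uint8)
        for w0 in range(0, clen, config.window_size):
            w1 = min(w0 + config.window_size, clen)
            t = targets[wk]
            wk += 1
            strong = rng.random(w1 - w0) < t
            pick = rng.integers(0, 2, size=w1 - w0)
            seq[w0:w1] = np.where(strong, _STRONG[pick], _WEAK[pick])
        seqs[name] = seq
        if config.repeat_fraction > 0:
            for s, e in _random_intervals(clen, config.repeat_fraction, 400, rng):
                rep_rows.append((name, s, e))
        if config.exon_fraction > 0:
            for s, e in _random_intervals(clen, config.exon_fraction, 150, rng):
                ex_rows.append((name, s, e))
    cols = ["chrom", "start", "end"]
    return seqs, pd.DataFrame(rep_rows, columns=cols), pd.DataFrame(ex_rows, columns=cols)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    ancestral: dict[str, np.ndarray]
    reference: dict[str, np.ndarray]
    repeats: pd.DataFrame
    exons: pd.DataFrame
    truth: pd.DataFrame  # one row per simulated site
    strata: list[dict]  # true parameters per stratum
    ingroup: list[str] = field(default_factory=list)
    outgroups: dict[str, list[str]] = field(default_factory=dict)
    #: haplotype membership of the derived allele, one bool row per site
    hap_matrix: np.ndarray | None = None


def _expected_cells(lam, B, theta_ratio, r, n, gc, target):
    idx = np.arange(1, n)
    a = likelihood.sfs_weight(idx, n, B)
    c = lam * gc / (1.0 - gc) * likelihood.sfs_weight(idx, n, -B)
    inv_i = 1.0 / idx
    scale = theta_ratio * (r * inv_i).sum() + (r * (a + c)).sum()
    theta_ws = target / scale
    theta_n = theta_ratio * theta_ws
    e_nn = theta_n * r * inv_i
    return {"SS": gc * e_nn, "WW": (1 - gc) * e_nn,
            "WS": theta_ws * r * a, "SW": theta_ws * r * c}, theta_n, theta_ws


def simulate_sites(config: SimulationConfig, genome, seed: int) -> SimulatedDataset:
    """Draw segregating sites on a genome built by :func:`make_genome`."""
    seqs, repeats, exons = genome
    rng = np.random.default_rng(seed)
    n = config.n_haplotypes
    idx = np.arange(1, n)
    r = (np.asarray(config.r_distortion, dtype=float)
         if config.r_distortion is not None else np.ones(n - 1))

    # mask and eligible positions, window GC for stratification
    masked = {c: np.zeros(len(s), dtype=bool) for c, s in seqs.items()}
    for bed in (repeats, exons):
        for chrom, s, e in bed.itertuples(index=False):
            masked[chrom][s:e] = True
    win_rows = []
    for chrom, seq in seqs.items():
        for w0 in range(0, len(seq), config.window_size):
            w1 = min(w0 + config.window_size, len(seq))
            ok = ~masked[chrom][w0:w1]
            if ok.sum() == 0:
                continue
            sub = seq[w0:w1][ok]
            gc = np.isin(sub, _STRONG).mean()
            win_rows.append((chrom, w0, w1, gc))
    wins = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "gc"])
    order = np.argsort(wins["gc"].to_numpy(), kind="mergesort")
    stratum_of_rank = np.minimum(
        np.arange(len(wins)) * config.n_strata // len(wins), config.n_strata - 1)
    wins["stratum"] = 0
    wins.loc[wins.index[order], "stratum"] = stratum_of_rank

    # eligible position pools per stratum, split by ancestral base class
    pools: list[dict[str, list[tuple[str, int]]]] = [
        {"S": [], "W": []} for _ in range(config.n_strata)]
    for chrom, w0, w1, _gc, st in wins.itertuples(index=False):
        ok = ~masked[chrom][w0:w1]
        pos = np.flatnonzero(ok) + w0
        strong = np.isin(seqs[chrom][pos], _STRONG)
        pools[st]["S"].extend((chrom, int(p)) for p in pos[strong])
        pools[st]["W"].extend((chrom, int(p)) for p in pos[~strong])

    total_eligible = sum(len(p["S"]) + len(p["W"]) for p in pools)
    truth_rows = []
    strata_truth = []
    hap_rows = []
    for st, pool in enumerate(pools):
        L_S, L_W = len(pool["S"]), len(pool["W"])
        if L_S + L_W == 0:
            continue
        frac = (st + 0.5) / config.n_strata
        lam = (config.lam_gradient[0] + (config.lam_gradient[1] - config.lam_gradient[0]) * frac
               if config.lam_gradient else config.lam)
        B = (config.B_gradient[0] + (config.B_gradient[1] - config.B_gradient[0]) * frac
             if config.B_gradient else config.B)
        gc = L_S / (L_S + L_W)
        target = config.target_snps * (L_S + L_W) / total_eligible
        cells, theta_n, theta_ws = _expected_cells(
            lam, B, config.theta_ratio, r, n, gc, target)
        counts = {cat: rng.poisson(mu) for cat, mu in cells.items()}
        n_from_s = int(counts["SS"].sum() + counts["SW"].sum())
        n_from_w = int(counts["WW"].sum() + counts["WS"].sum())
        if n_from_s > L_S or n_from_w > L_W:
            raise ValueError("demanded SNP count exceeds eligible bases; "
                             "lower target_snps or enlarge the genome")
        pick_s = rng.choice(L_S, size=n_from_s, replace=False)
        pick_w = rng.choice(L_W, size=n_from_w, replace=False)
        ps, pw = 0, 0
        for cat in ("SS", "SW", "WW", "WS"):
            from_strong = cat in ("SS", "SW")
            for i in idx:
                for _ in range(int(counts[cat][i - 1])):
                    if from_strong:
                        chrom, pos0 = pool["S"][pick_s[ps]]
                        ps += 1
                    else:
                        chrom, pos0 = pool["W"][pick_w[pw]]
                        pw += 1
                    anc = chr(seqs[chrom][pos0])
                    if cat == "SS":
                        der = "C" if anc == "G" else "G"
                    elif cat == "WW":
                        der = "T" if anc == "A" else "A"
                    elif cat == "SW":
                        der = "AT"[rng.integers(0, 2)]
                    else:
                        der = "GC"[rng.integers(0, 2)]
                    carriers = np.zeros(n, dtype=bool)
                    carriers[rng.choice(n, size=int(i), replace=False)] = True
                    mis = bool(rng.random() < config.misorientation)
                    truth_rows.append({
                        "chrom": chrom, "pos": pos0 + 1, "anc": anc, "der": der,
                        "category": cat, "i": int(i), "stratum": st,
                        "misoriented": mis})
                    hap_rows.append(carriers)
        strata_truth.append({"stratum": st, "lambda": lam, "B": B,
                             "theta_N": theta_n, "theta_WS": theta_ws,
                             "gc": gc, "L_S": L_S, "L_W": L_W})
    truth = pd.DataFrame(truth_rows).sort_values(["chrom", "pos"])
    order = truth.index.to_numpy()
    truth = truth.reset_index(drop=True)
    hap = np.asarray(hap_rows, dtype=bool)[order] if hap_rows else None

    # reference genome: the ancestral genome, except where the sampled
    # reference haplotype carries the derived allele
    reference = {c: s.copy() for c, s in seqs.items()}
    ref_is_der = np.zeros(len(truth), dtype=bool)
    if config.reference_bias and len(truth):
        ref_is_der = rng.random(len(truth)) < truth["i"].to_numpy() / n
        for k in np.flatnonzero(ref_is_der):
            row = truth.iloc[k]
            reference[row["chrom"]][row["pos"] - 1] = ord(row["der"])
    truth["ref_is_derived"] = ref_is_der

    ingroup = [f"ing_{j + 1:02d}" for j in range(n // 2)]
    outgroups = {f"og{p + 1}": [f"og{p + 1}_{j + 1}" for j in range(sz)]
                 for p, sz in enumerate(config.outgroup_sizes)}
    return SimulatedDataset(config=config, ancestral=seqs, reference=reference,
                            repeats=repeats, exons=exons, truth=truth,
                            strata=strata_truth, ingroup=ingroup,
                            outgroups=outgroups, hap_matrix=hap)


def simulate_spectra(lam: float, B: float, n: int, gc: float, target_snps: float,
                     theta_ratio: float = 1.0, r=None, seed: int = 0,
                     poisson: bool = True) -> CategorySpectra:
    """Spectra-level shortcut: Poisson cell counts from the expected law.

    Bypasses genome construction for parameter-recovery and calibration
    studies; ``poisson=False`` returns the expected (fractional) spectra.
    """
    rng = np.random.default_rng(seed)
    r = np.ones(n - 1) if r is None else np.asarray(r, dtype=float)
    cells, _, _ = _expected_cells(lam, B, theta_ratio, r, n, gc, target_snps)
    counts = {cat: (rng.poisson(mu).astype(float) if poisson else mu)
              for cat, mu in cells.items()}
    L_total = 1e6
    return CategorySpectra(n=n, counts=counts, L_W=(1 - gc) * L_total, L_S=gc * L_total)


def wright_fisher_sfs(N: int, n: int, B: float, n_mutations: int, seed: int,
                      generations: int | None = None) -> np.ndarray:
    """Forward Wright-Fisher check of the frequency-class weights.

    Injects ``n_mutations`` new mutations (one copy each) into a population
    of N haploid genomes and propagates each with per-generation selection
    coefficient s = B/(2N) favoring the derived allele, so the scaled
    strength 2Ns of the diffusion matches the SFS weight's exponent B.
    Under steady mutational influx the expected number of segregating sites
    observed in class i of an n-genome sample is proportional to the
    occupation measure of the trajectory, so every generation of every
    trajectory contributes its binomial class probabilities to the
    histogram.  Returns the accumulated class weights over 1..n-1, whose
    shape estimates F_i(B) up to a constant.
    """
    rng = np.random.default_rng(seed)
    gens = generations if generations is not None else 20 * N
    s = B / (2 * N)
    i_arr = np.arange(1, n)
    log_binom = (gammaln(n + 1) - gammaln(i_arr + 1) - gammaln(n - i_arr + 1))
    hist = np.zeros(n - 1)
    for _ in range(n_mutations):
        x = 1.0 / N
        for _ in range(gens):
            # Rao-Blackwellized class probabilities at the current frequency
            hist += np.exp(log_binom + i_arr * np.log(x)
                           + (n - i_arr) * np.log1p(-x))
            p = x * (1 + s) / (x * (1 + s) + (1 - x))
            x = rng.binomial(N, p) / N
            if x == 0.0 or x == 1.0:
                break
    return hist


# ---------------------------------------------------------------------------
# Writers


def write_fasta(path, seqs: dict[str, np.ndarray], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            s = seqs[name].tobytes().decode()
            fh.write(f">{name}\n")
            for k in range(0, len(s), width):
                fh.write(s[k:k + width] + "\n")


def write_bed(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_vcf(path, dataset: SimulatedDataset) -> None:
    """Emit the simulated variants as a plain-text VCFv4.2 with GT fields."""
    cfg = dataset.config
    n = cfg.n_haplotypes
    samples = list(dataset.ingroup)
    for pop in dataset.outgroups:
        samples.extend(dataset.outgroups[pop])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbgc-simulate\n")
        for chrom, seq in dataset.reference.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k, row in enumerate(dataset.truth.itertuples()):
            ref_is_der = bool(row.ref_is_derived)
            ref = row.der if ref_is_der else row.anc
            alt = row.anc if ref_is_der else row.der
            der_idx = 0 if ref_is_der else 1
            anc_idx = 1 - der_idx
            carriers = dataset.hap_matrix[k]
            gts = []
            for j in range(n // 2):
                a = der_idx if carriers[2 * j] else anc_idx
                b = der_idx if carriers[2 * j + 1] else anc_idx
                gts.append(f"{a}/{b}")
            og_idx = der_idx if row.misoriented else anc_idx
            for pop in dataset.outgroups:
                gts.extend([f"{og_idx}/{og_idx}"] * len(dataset.outgroups[pop]))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_dataset(out_dir, dataset: SimulatedDataset, name: str = "sim") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / f"{name}_ref.fa",
        "ancestral": out / f"{name}_ancestral_truth.fa",
        "repeats": out / f"{name}_repeats.bed",
        "exons": out / f"{name}_exons.bed",
        "vcf": out / f"{name}.vcf",
        "truth": out / f"{name}_truth.json",
        "sites": out / f"{name}_truth_sites.tsv",
    }
    write_fasta(paths["reference"], dataset.reference)
    write_fasta(paths["ancestral"], dataset.ancestral)
    write_bed(paths["repeats"], dataset.repeats)
    write_bed(paths["exons"], dataset.exons)
    write_vcf(paths["vcf"], dataset)
    dataset.truth.to_csv(paths["sites"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump({"config": {k: list(v) if isinstance(v, tuple) else v
                              for k, v in asdict(dataset.config).items()},
                   "strata": dataset.strata,
                   "ingroup": dataset.ingroup,
                   "outgroups": dataset.outgroups,
                   "n_sites": int(len(dataset.truth))},
                  fh, indent=1, sort_keys=True)
    return paths


_TOY_VCF = """\
##fileformat=VCFv4.2
##source=gbgc-toy
##contig=<ID=toy_chr,length=100>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ting_01\ting_02\tog1_1\tog2_1
toy_chr\t10\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\t1/1\t1/1
toy_chr\t20\t.\tC\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
toy_chr\t30\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\t0/0
toy_chr\t40\t.\tA\tC,T\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\t0/0
toy_chr\t50\t.\tT\tC\t.\tPASS\t.\tGT\t0/1\t1/1\t0/0\t0/0
"""

_TOY_SEQ = ("ACGTACGTAGCGTACGTACCTACGTACGTAACGTACGTACATACGTACGTTACGTACGTA"
            "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGTA")
# positions (1-based): 10=G, 20=C, 30=A, 40=A, 50=T match the toy VCF REFs


def write_toy_fixture(out_dir) -> dict[str, Path]:
    """Five-record hand-built VCF: one clean SNP, one exonic, one with a
    missing ingroup genotype, one triallelic, one inside a repeat."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "toy.vcf", "reference": out / "toy_ref.fa",
             "repeats": out / "toy_repeats.bed", "exons": out / "toy_exons.bed"}
    paths["vcf"].write_text(_TOY_VCF)
    with open(paths["reference"], "w") as fh:
        fh.write(">toy_chr\n")
        for k in range(0, len(_TOY_SEQ), 60):
            fh.write(_TOY_SEQ[k:k + 60] + "\n")
    paths["repeats"].write_text("toy_chr\t45\t55\n")
    paths["exons"].write_text("toy_chr\t15\t25\n")
    return paths


def write_fixture_suite(out_dir, seed: int) -> dict[str, dict[str, Path]]:
    """The canonical small fixtures used across the test suites.

    Byte-stable for a fixed seed: the toy 5-record VCF, a 10 kb genome, a
    default-scale recovery genome, and a two-population contrast pair of
    spectra with truth files.
    """
    out = Path(out_dir)
    suite: dict[str, dict[str, Path]] = {"toy": write_toy_fixture(out / "toy")}

    small_cfg = SimulationConfig(genome_length=10_000, n_contigs=1, window_size=500,
                                 target_snps=150, repeat_fraction=0.05)
    small = simulate_sites(small_cfg, make_genome(small_cfg, seed + 1), seed + 2)
    suite["small"] = write_dataset(out / "small", small, "small")

    rec_cfg = SimulationConfig()
    rec = simulate_sites(rec_cfg, make_genome(rec_cfg, seed + 3), seed + 4)
    suite["recovery"] = write_dataset(out / "recovery", rec, "recovery")

    contrast = {}
    for off, (tag, (lam, B)) in enumerate({"kaz_juv_like": (4.15, 0.79),
                                           "swe_sin_like": (2.99, 0.21)}.items()):
        sp = simulate_spectra(lam, B, n=20, gc=0.32, target_snps=20_000,
                              seed=seed + 5 + off)
        p = out / "contrast" / f"{tag}_spectra.tsv"
        p.parent.mkdir(parents=True, exist_ok=True)
        sp.to_tsv(p)
        tp = out / "contrast" / f"{tag}_truth.json"
        with open(tp, "w") as fh:
            json.dump({"lambda": lam, "B": B, "gc": 0.32, "n": 20}, fh, sort_keys=True)
        contrast[tag] = p
    suite["contrast"] = contrast
    return suite
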