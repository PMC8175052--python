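"""SNP filtering, outgroup polarization and the masked ancestral genome.

Unfolded frequency spectra need each SNP oriented into ancestral and derived
alleles.  Orientation here uses invariant sites in one or two outgroup
populations: an allele observed homozygously in every consulted outgroup
individual is taken as ancestral, provided it is one of the two ingroup
alleles.  Two schemes are supported:

* strict  - every outgroup individual, no missing data tolerated;
* liberal - one designated (highest-mean-depth) individual per outgroup
  population, tolerating one missing allele per individual.

Ancestral alleles are then written back into the reference sequence to build
a model of the ancestral genome, with repeats and exons masked, from which
local GC content and trinucleotide contexts (for the CpG-prone filter) are
read.  Coordinates: VCF positions are 1-based; BED intervals and all
internal intervals are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STRONG = frozenset("GC")
WEAK = frozenset("AT")
_BASES = frozenset("ACGT")

#: dinucleotides marking a CpG-prone context (N = masked or unknown base)
CPG_PRONE_DINUCLEOTIDES = frozenset({"CG", "TG", "CA", "NG", "TN", "CN", "NA"})


class VCFParseError(ValueError):
    pass


@dataclass
class VariantRecord:
    """One VCF site reduced to what polarization needs.

    ``outgroup_gts`` maps outgroup population name to a list of per-individual
    allele-index pairs (0 = ref, 1+ = alt order; None = missing call).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    n_ingroup: int  # haploid ingroup sample size
    ingroup_alt: int  # alt allele count among ingroup haplotypes
    ingroup_missing: int  # missing ingroup haploid calls
    outgroup_gts: dict[str, list[tuple[int | None, int | None]]] = field(default_factory=dict)

    @property
    def is_biallelic_snp(self) -> bool:
        return (len(self.alts) == 1 and len(self.ref) == 1 and len(self.alts[0]) == 1
                and self.ref in _BASES and self.alts[0] in _BASES)


@dataclass
class PolarizedSite:
    chrom: str
    pos: int
    ancestral_allele: str
    derived_allele: str
    category: str
    derived_count: int
    n: int
    context: str = "NNN"
    cpg_prone: bool | None = None


@dataclass
class Rejection:
    chrom: str
    pos: int
    reason: str


def classify_mutation(ancestral: str, derived: str) -> str:
    """Mutation category from the strong/weak classes of the two alleles."""
    ancestral, derived = ancestral.upper(), derived.upper()
    if ancestral == derived:
        raise ValueError("ancestral and derived alleles must differ")
    if ancestral not in _BASES or derived not in _BASES:
        raise ValueError("alleles must be A, C, G or T")
    a = "S" if ancestral in STRONG else "W"
    d = "S" if derived in STRONG else "W"
    return a + d


def flag_cpg_prone(context: str) -> bool:
    """True iff either dinucleotide overlapping the focal (middle) base is prone."""
    context = context.upper()
    if len(context) != 3:
        raise ValueError("context must be an ancestral trinucleotide")
    return (context[:2] in CPG_PRONE_DINUCLEOTIDES
            or context[1:] in CPG_PRONE_DINUCLEOTIDES)


# ---------------------------------------------------------------------------
# VCF / BED reading


def load_variants(vcf_path, ingroup: Sequence[str],
                  outgroups: Mapping[str, Sequence[str]]) -> list[VariantRecord]:
    """Read a VCF into VariantRecords given ingroup/outgroup sample names."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    try:
        in_idx = [samples.index(s) for s in ingroup]
        out_idx = {pop: [samples.index(s) for s in ss] for pop, ss in outgroups.items()}
    except ValueError as exc:
        raise VCFParseError(f"sample missing from VCF header: {exc}") from exc
    records = []
    rec_no = 0
    try:
        for v in vcf:
            rec_no += 1
            gts = v.genotypes  # [a1, a2, phased] per sample
            alt_count = 0
            missing = 0
            for j in in_idx:
                for a in gts[j][:2]:
                    if a < 0:
                        missing += 1
                    elif a > 0:
                        alt_count += 1
            out_gts = {}
            for pop, idxs in out_idx.items():
                out_gts[pop] = [tuple(a if a >= 0 else None for a in gts[j][:2])
                                for j in idxs]
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alts=tuple(v.ALT),
                n_ingroup=2 * len(in_idx), ingroup_alt=alt_count,
                ingroup_missing=missing, outgroup_gts=out_gts))
    except Exception as exc:  # cyvcf2 raises on malformed body lines
        raise VCFParseError(f"malformed VCF record #{rec_no + 1} in {vcf_path}: {exc}") from exc
    return records


def mean_depth_per_sample(vcf_path) -> pd.Series:
    """Mean FORMAT/DP per sample, for designating liberal-scheme individuals."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    total = np.zeros(len(vcf.samples))
    n = 0
    for v in vcf:
        d = v.gt_depths.astype(float)
        d[d < 0] = np.nan
        total += np.nan_to_num(d)
        n += 1
    if n == 0:
        raise VCFParseError(f"no records in {vcf_path}")
    return pd.Series(total / n, index=vcf.samples)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3 file; intervals are merged per chromosome."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return merge_intervals(df)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    out = []
    for chrom, grp in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


class _IntervalIndex:
    """Point-in-interval lookups over merged, sorted intervals."""

    def __init__(self, *beds: pd.DataFrame | None):
        frames = [b for b in beds if b is not None and len(b)]
        merged = (merge_intervals(pd.concat(frames, ignore_index=True))
                  if frames else pd.DataFrame(columns=["chrom", "start", "end"]))
        self._by_chrom = {
            chrom: (grp["start"].to_numpy(), grp["end"].to_numpy())
            for chrom, grp in merged.groupby("chrom")}
        self.intervals = merged

    def contains(self, chrom: str, pos0: int) -> bool:
        se = self._by_chrom.get(chrom)
        if se is None:
            return False
        starts, ends = se
        k = np.searchsorted(starts, pos0, side="right") - 1
        return k >= 0 and pos0 < ends[k]


def filter_variants(records: Sequence[VariantRecord],
                    repeat_bed: pd.DataFrame | None = None,
                    exon_bed: pd.DataFrame | None = None) -> list[VariantRecord]:
    """Keep biallelic SNPs outside repeats/exons with no missing ingroup call."""
    mask = _IntervalIndex(repeat_bed, exon_bed)
    kept = [v for v in records
            if v.is_biallelic_snp
            and v.ingroup_missing == 0
            and not mask.contains(v.chrom, v.pos - 1)]
    kept.sort(key=lambda v: (v.chrom, v.pos))
    return kept


# ---------------------------------------------------------------------------
# Polarization


def _orient(variant: VariantRecord, anc_idx: int) -> PolarizedSite | Rejection:
    if anc_idx > 1 or not variant.is_biallelic_snp:
        return Rejection(variant.chrom, variant.pos, "third_allele")
    anc = variant.ref if anc_idx == 0 else variant.alts[0]
    der = variant.alts[0] if anc_idx == 0 else variant.ref
    n = variant.n_ingroup
    i = variant.ingroup_alt if anc_idx == 0 else n - variant.ingroup_alt
    if not 1 <= i <= n - 1:
        return Rejection(variant.chrom, variant.pos, "ingroup_invariant")
    return PolarizedSite(chrom=variant.chrom, pos=variant.pos,
                         ancestral_allele=anc, derived_allele=der,
                         category=classify_mutation(anc, der),
                         derived_count=i, n=n)


def polarize_strict(variant: VariantRecord,
                    outgroup_populations: Sequence[str] | None = None
                    ) -> PolarizedSite | Rejection:
    """Ancestral allele = the one allele all outgroup individuals carry
    homozygously; no missing outgroup data tolerated."""
    pops = outgroup_populations or list(variant.outgroup_gts)
    alleles = set()
    for pop in pops:
        for gt in variant.outgroup_gts[pop]:
            if gt[0] is None or gt[1] is None:
                return Rejection(variant.chrom, variant.pos, "outgroup_missing")
            alleles.update(gt)
    if not alleles:
        return Rejection(variant.chrom, variant.pos, "outgroup_missing")
    if len(alleles) > 1:
        return Rejection(variant.chrom, variant.pos, "outgroup_polymorphic")
    return _orient(variant, alleles.pop())


def polarize_liberal(variant: VariantRecord,
                     designated: Mapping[str, int]) -> PolarizedSite | Rejection:
    """Strict orientation rule on one designated individual per outgroup
    population, tolerating one missing allele per individual.

    ``designated`` maps population name to the index of its chosen (highest
    mean depth) individual within that population's genotype list.
    """
    alleles = set()
    for pop, k in designated.items():
        gt = variant.outgroup_gts[pop][k]
        called = [a for a in gt if a is not None]
        if not called:  # both alleles missing exceeds the one-allele tolerance
            return Rejection(variant.chrom, variant.pos, "outgroup_missing")
        alleles.update(called)
    if len(alleles) > 1:
        return Rejection(variant.chrom, variant.pos, "outgroup_polymorphic")
    return _orient(variant, alleles.pop())


def polarize_all(records: Sequence[VariantRecord], scheme: str = "strict",
                 designated: Mapping[str, int] | None = None
                 ) -> tuple[list[PolarizedSite], list[Rejection]]:
    """Polarize every record; returns accepted sites and logged rejections."""
    sites, rejections = [], []
    for v in records:
        if scheme == "strict":
            res = polarize_strict(v)
        elif scheme == "liberal":
            if designated is None:
                designated = {pop: 0 for pop in v.outgroup_gts}
            res = polarize_liberal(v, designated)
        else:
            raise ValueError("scheme must be 'strict' or 'liberal'")
        (sites if isinstance(res, PolarizedSite) else rejections).append(res)
    return sites, rejections


# ---------------------------------------------------------------------------
# Ancestral genome


@dataclass
class MaskedAncestralGenome:
    """Reference sequence with derived alleles replaced by ancestral ones and
    repeat/exon intervals masked.  ``seqs`` holds uppercase byte arrays,
    ``mask`` boolean arrays (True = masked); N bases are treated as masked
    for all base counting."""

    seqs: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    substituted: list[tuple[str, int]] = field(default_factory=list)

    def _counting_mask(self, chrom: str) -> np.ndarray:
        return self.mask[chrom] | (self.seqs[chrom] == ord("N"))

    def base_counts(self, chrom: str | None = None,
                    start: int | None = None, end: int | None = None
                    ) -> tuple[int, int]:
        """(L_W, L_S): unmasked weak and strong base counts."""
        chroms = [chrom] if chrom else list(self.seqs)
        L_W = L_S = 0
        for c in chroms:
            seq = self.seqs[c][start:end]
            ok = ~self._counting_mask(c)[start:end]
            s = ((seq == ord("G")) | (seq == ord("C"))) & ok
            w = ((seq == ord("A")) | (seq == ord("T"))) & ok
            L_S += int(s.sum())
            L_W += int(w.sum())
        return L_W, L_S

    def gc_content(self) -> float:
        L_W, L_S = self.base_counts()
        return L_S / (L_W + L_S)

    def context(self, chrom: str, pos: int) -> str:
        """Ancestral trinucleotide centered on 1-based ``pos``; masked,
        unknown or out-of-range neighbors become N."""
        seq, cmask = self.seqs[chrom], self._counting_mask(chrom)
        out = []
        for p0 in range(pos - 2, pos + 1):
            if p0 < 0 or p0 >= len(seq) or (cmask[p0] and p0 != pos - 1):
                out.append("N")
            else:
                out.append(chr(seq[p0]))
        return "".join(out)

    def to_fasta(self, path, width: int = 60) -> None:
        """Write with masked positions lowercased (soft masking)."""
        with open(path, "w") as fh:
            for chrom in self.seqs:
                arr = self.seqs[chrom].copy()
                m = self.mask[chrom] & (arr != ord("N"))
                arr[m] += 32  # uppercase -> lowercase
                s = arr.tobytes().decode()
                fh.write(f">{chrom}\n")
                for k in range(0, len(s), width):
                    fh.write(s[k:k + width] + "\n")


def _load_fasta(path) -> dict[str, np.ndarray]:
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True)
    return {name: np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8).copy()
            for name in fa.keys()}


def build_ancestral_genome(reference_fasta, polarized_sites: Sequence[PolarizedSite],
                           repeat_bed: pd.DataFrame | None = None,
                           exon_bed: pd.DataFrame | None = None
                           ) -> MaskedAncestralGenome:
    """Substitute ancestral alleles into the reference and apply masks.

    Where the reference carries the derived allele the ancestral allele is
    written instead; sites where the reference already holds the ancestral
    allele are untouched.  Substitutions under a masked interval trigger a
    warning and stay excluded from GC accounting (mask wins).
    """
    seqs = _load_fasta(reference_fasta)
    mask = {c: np.zeros(len(s), dtype=bool) for c, s in seqs.items()}
    for bed in (repeat_bed, exon_bed):
        if bed is None:
            continue
        for chrom, start, end in bed.itertuples(index=False):
            if chrom in mask:
                mask[chrom][start:end] = True
    seen = set()
    ag = MaskedAncestralGenome(seqs=seqs, mask=mask)
    for site in polarized_sites:
        key = (site.chrom, site.pos)
        if key in seen:
            raise ValueError(f"duplicate polarized site at {key}")
        seen.add(key)
        p0 = site.pos - 1
        ref_base = chr(seqs[site.chrom][p0])
        if ref_base == site.derived_allele:
            if mask[site.chrom][p0]:
                warnings.warn(f"substitution at masked position {key}; "
                              "site excluded from GC accounting", stacklevel=2)
            seqs[site.chrom][p0] = ord(site.ancestral_allele)
            ag.substituted.append(key)
        elif ref_base != site.ancestral_allele:
            warnings.warn(f"reference base {ref_base} at {key} matches neither "
                          "ancestral nor derived allele; left unchanged", stacklevel=2)
    return ag


def annotate_contexts(sites: Sequence[PolarizedSite],
                      genome: MaskedAncestralGenome) -> None:
    """Fill ``context`` and ``cpg_prone`` in place from the ancestral genome."""
    for s in sites:
        s.context = genome.context(s.chrom, s.pos)
        s.cpg_prone = flag_cpg_prone(s.context)


def sites_to_frame(sites: Sequence[PolarizedSite]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "pos": s.pos, "anc": s.ancestral_allele,
        "der": s.derived_allele, "category": s.category,
        "i": s.derived_count, "n": s.n, "context": s.context,
        "cpg_prone": s.cpg_prone} for s in sites])


def write_sites_tsv(sites: Sequence[PolarizedSite], path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
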