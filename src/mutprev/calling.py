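"""Low-VAF variant calling against an internal-standard limit of blank.

Because the synthetic IS experiences the same library-prep and sequencing
errors as the native template but carries no biology, the VAF of each
substitution at each IS position is a direct measurement of the technical
noise floor - the limit of blank (LOB).  An observed NT variant count k at a
molecule-scale depth n is tested against that floor with a one-sided exact
Poisson tail, P(X >= k) with X ~ Poisson(LOB x n), Bonferroni-corrected over
the 193 analyzable bases x 3 possible substitutions = 579 tests.  Calls must
additionally be supported by more than 5 NT molecules and exceed 0.01% VAF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import BASES, TargetPanel, substitution_class
from .reads import SamplePileup

DEFAULT_ALPHA = 0.05
MIN_MOLECULES = 5  # strict: a call needs > 5 supporting molecules
MIN_VAF = 1e-4  # strict: VAF > 0.01%


class LobError(RuntimeError):
    """LOB table unusable (zero IS depth or missing entries)."""


@dataclass
class LobTable:
    """Per-position, per-substitution limit of blank measured from IS reads.

    ``lob[target]`` is a (4, L) array of LOB VAFs with NaN at the reference
    base and at masked positions; ``is_depth[target]`` holds the IS read
    depth per position.
    """

    lob: dict[str, np.ndarray] = field(default_factory=dict)
    is_depth: dict[str, np.ndarray] = field(default_factory=dict)

    def n_entries(self) -> int:
        return int(sum(np.isfinite(m).sum() for m in self.lob.values()))

    def get(self, target: str, pos: int, alt_idx: int) -> float:
        v = float(self.lob[target][alt_idx, pos])
        if not np.isfinite(v):
            raise LobError(f"no LOB entry for {target}:{pos} alt {alt_idx}")
        return v


@dataclass
class VariantCall:
    target: str
    pos: int  # 0-based amplicon offset
    chrom: str
    genomic_pos: int  # 1-based
    ref: str
    alt: str
    nt_molecules: int
    nt_depth: int
    vaf: float
    lob: float
    p_value: float
    significant: bool
    passes_molecule_filter: bool
    passes_vaf_filter: bool
    sig_class: str
    hotspot: bool | None = None
    consequence: str | None = None


def estimate_lob(sp: SamplePileup, panel: TargetPanel,
                 zero_floor: bool = True) -> LobTable:
    """Measure the LOB for every analyzable TP53 position-substitution.

    LOB = IS variant reads / IS depth, floored at 0.5/depth when no variant
    read was seen (a zero blank rate would make any observation infinitely
    significant; the half-count floor is the standard continuity choice).
    """
    table = LobTable()
    for tname in panel.tp53_targets:
        amp = panel.amplicons[tname]
        mat = sp.is_[tname]
        ref = amp.reference
        depth = mat.sum(axis=0).astype(float)
        lob = np.full((4, amp.length), np.nan)
        analyzable = amp.analyzable_positions
        if (depth[analyzable] == 0).any():
            raise LobError(
                f"{tname}: zero IS depth inside the analyzable span")
        for pos in analyzable:
            d = depth[pos]
            for alt in range(4):
                if alt == ref[pos]:
                    continue
                rate = mat[alt, pos] / d
                if zero_floor:
                    rate = max(rate, 0.5 / d)
                lob[alt, pos] = rate
        table.lob[tname] = lob
        table.is_depth[tname] = depth
    return table


def pet_test(nt_variant_molecules: int, nt_depth: int, lob: float) -> float:
    """One-sided upper-tail exact Poisson p-value.

    P(X >= k) with X ~ Poisson(lob x depth); exact tail, no normal
    approximation.  k = 0 returns 1.
    """
    if nt_depth <= 0:
        raise ValueError("nt_depth must be > 0")
    lam = lob * nt_depth
    return float(stats.poisson.sf(nt_variant_molecules - 1, lam))


def pet_test_two_sample(nt_count: int, nt_depth: int, is_count: int,
                        is_depth: int) -> float:
    """Two-sample exact variant: conditional binomial test of the NT count
    given the pooled count, with success probability depth_nt/(depth_nt+
    depth_is).  Available behind a configuration switch; the one-sample test
    against the measured LOB is the default."""
    total = nt_count + is_count
    if total == 0:
        return 1.0
    p = nt_depth / (nt_depth + is_depth)
    return float(stats.binomtest(nt_count, total, p,
                                 alternative="greater").pvalue)


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, n_positions: int = 193,
                         n_subs_per_position: int = 3) -> float:
    """Corrected per-test alpha: alpha / (positions x substitutions)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / (n_positions * n_subs_per_position)


def call_variants(nt_pileup: SamplePileup, lob: LobTable, panel: TargetPanel,
                  alpha: float = DEFAULT_ALPHA,
                  min_molecules: int = MIN_MOLECULES,
                  min_vaf: float = MIN_VAF,
                  two_sample: bool = False) -> list[VariantCall]:
    """Call variants on a molecule-scale NT pileup.

    A site-substitution is called iff its PET p-value beats the Bonferroni
    threshold AND it is supported by strictly more than ``min_molecules``
    NT molecules AND its VAF strictly exceeds ``min_vaf``.
    """
    n_positions = panel.analyzable_bp
    threshold = bonferroni_threshold(alpha, n_positions, 3)
    calls: list[VariantCall] = []
    for tname in panel.tp53_targets:
        amp = panel.amplicons[tname]
        mat = nt_pileup.nt[tname]
        ref = amp.reference
        for pos in amp.analyzable_positions:
            col = mat[:, pos]
            depth = int(col.sum())
            if depth == 0:
                continue
            for alt in range(4):
                if alt == ref[pos]:
                    continue
                k = int(col[alt])
                if k == 0:
                    continue
                lob_v = lob.get(tname, int(pos), alt)
                if two_sample:
                    d = lob.is_depth[tname][pos]
                    p = pet_test_two_sample(
                        k, depth, int(round(lob_v * d)), int(d))
                else:
                    p = pet_test(k, depth, lob_v)
                vaf = k / depth
                sig = p < threshold
                mol_ok = k > min_molecules
                vaf_ok = vaf > min_vaf
                if sig and mol_ok and vaf_ok:
                    calls.append(VariantCall(
                        target=tname, pos=int(pos), chrom=amp.chrom,
                        genomic_pos=amp.genomic_start + int(pos),
                        ref=BASES[ref[pos]], alt=BASES[alt],
                        nt_molecules=k, nt_depth=depth, vaf=vaf, lob=lob_v,
                        p_value=p, significant=sig,
                        passes_molecule_filter=mol_ok,
                        passes_vaf_filter=vaf_ok,
                        sig_class=substitution_class(BASES[ref[pos]],
                                                     BASES[alt])))
    calls.sort(key=lambda c: (c.target, c.pos, c.alt))
    return calls


def unique_mutation_count(calls: list[VariantCall]) -> int:
    """Unique mutation clones: distinct (target, position, alt) triples."""
    return len({(c.target, c.pos, c.alt) for c in calls})


# --------------------------------------------------------------- annotation

@dataclass(frozen=True)
class CodonContext:
    """Reading-frame anchor for one target: the amplicon offset at which an
    in-frame codon starts (forward strand)."""

    target: str
    frame_start: int


def load_codon_context(path) -> dict[str, CodonContext]:
    """GFF-lite TSV: columns target, frame_start."""
    out = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            target, frame_start = line.split()[:2]
            out[target] = CodonContext(target, int(frame_start))
    return out


def load_hotspots(path) -> set[tuple[str, int]]:
    """Hotspot sites from BED (chrom, 0-based start/end) as 1-based points."""
    sites: set[tuple[str, int]] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split()[:3]
            for g in range(int(s) + 1, int(e) + 1):
                sites.add((chrom, g))
    return sites


def annotate_variant(call: VariantCall, panel: TargetPanel,
                     codon_context: dict[str, CodonContext] | None = None,
                     hotspots: set[tuple[str, int]] | None = None
                     ) -> VariantCall:
    """Add consequence (from codon translation) and hotspot flag in place."""
    from Bio.Seq import Seq

    if hotspots is not None:
        call.hotspot = (call.chrom, call.genomic_pos) in hotspots
    if codon_context and call.target in codon_context:
        ctx = codon_context[call.target]
        amp = panel.amplicons[call.target]
        offset = call.pos - ctx.frame_start
        if offset < 0:
            raise ValueError(
                f"{call.target}:{call.pos} upstream of the reading frame")
        codon_start = ctx.frame_start + 3 * (offset // 3)
        if codon_start + 3 > amp.length:
            raise ValueError(
                f"{call.target}: reading frame inconsistent with "
                f"amplicon length")
        codon = amp.sequence[codon_start:codon_start + 3]
        mutant = list(codon)
        mutant[call.pos - codon_start] = call.alt
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq("".join(mutant)).translate())
        if aa_alt == aa_ref:
            call.consequence = "silent"
        elif aa_alt == "*":
            call.consequence = "nonsense"
        else:
            call.consequence = "missense"
    return call


# --------------------------------------------------------------------- VCF

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mutprev
##INFO=<ID=NTMOL,Number=1,Type=Integer,Description="NT variant molecules">
##INFO=<ID=NTDEPTH,Number=1,Type=Integer,Description="NT molecule depth">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">
##INFO=<ID=LOB,Number=1,Type=Float,Description="Limit of blank VAF">
##INFO=<ID=PETP,Number=1,Type=Float,Description="Poisson exact test p-value">
##INFO=<ID=SIGCLASS,Number=1,Type=String,Description="Substitution class">
##INFO=<ID=HOTSPOT,Number=0,Type=Flag,Description="Known hotspot site">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: list[VariantCall], path,
              contigs: tuple[str, ...] = ("chr11", "chr17")) -> None:
    seen = sorted({c.chrom for c in calls} | set(contigs))
    with open(path, "w") as fh:
        header = VCF_HEADER.split("#CHROM")
        fh.write(header[0])
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM" + header[1])
        for c in calls:
            info = (f"NTMOL={c.nt_molecules};NTDEPTH={c.nt_depth};"
                    f"VAF={c.vaf:.6g};LOB={c.lob:.6g};PETP={c.p_value:.6g};"
                    f"SIGCLASS={c.sig_class.replace('>', '')}")
            if c.hotspot:
                info += ";HOTSPOT"
            fh.write(f"{c.chrom}\t{c.genomic_pos}\t.\t{c.ref}\t{c.alt}\t.\t"
                     f"PASS\t{info}\n")
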