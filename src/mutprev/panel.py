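"""Amplicon target panel: references, primers, IS dinucleotides, analyzable mask.

The assay interrogates three TP53 amplicons (exons 5-7, jointly spanning 193
analyzable bases) plus one SCGB1A1 amplicon used for competitive molecule
counting.  Each target has a synthetic internal-standard (IS) counterpart that
is identical to the native template (NT) except for substituted dinucleotides
roughly every 50 bases; those dinucleotide positions, one flanking base on
each side, and the primer spans are excluded from variant analysis.

Coordinates are 0-based half-open within each amplicon; genomic anchors are
carried along for 1-based VCF output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: substitution applied to build IS alleles from the NT reference (transversion
#: partner, so the IS allele is never confusable with a transition error)
IS_SUBSTITUTION = {"A": "C", "C": "A", "G": "T", "T": "G"}

TP53_TARGETS = ("TP53.5", "TP53.6", "TP53.7")
SCGB1A1 = "SCGB1A1"

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
#: substitution classes reported on the pyrimidine strand; C>A is the tobacco
#: signature, C>T and T>C the age signatures
SIGNATURE_CLASSES = ("C>A", "C>T", "T>C", "other")


def substitution_class(ref: str, alt: str) -> str:
    """Pyrimidine-context substitution class (G>T counts as C>A, etc.)."""
    if ref not in BASE_INDEX or alt not in BASE_INDEX or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    cls = f"{ref}>{alt}"
    return cls if cls in SIGNATURE_CLASSES else "other"

_ENCODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 indices (A=0,C=1,G=2,T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.argmax(arr < 0))]
        raise ValueError(f"non-ACGT base {bad!r} in sequence")
    return arr.copy()


def decode_seq(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


@dataclass(frozen=True)
class Amplicon:
    """One amplicon target with its IS design and analyzable mask."""

    name: str
    chrom: str
    genomic_start: int  # 1-based genomic coordinate of amplicon position 0
    sequence: str  # NT reference, full amplicon including primers
    primer_left: int  # length of the 5' primer span
    primer_right: int  # length of the 3' primer span
    dinucleotide_positions: tuple[int, ...]  # substituted bases (IS design)
    eccl_tag_positions: dict[int, tuple[int, ...]] = field(default_factory=dict)
    # rung index (2..n) -> additionally substituted positions identifying the
    # lower rungs of the external complexity calibration ladder (ECCL).

    def __post_init__(self):
        L = len(self.sequence)
        for p in self.dinucleotide_positions:
            if not (self.primer_left <= p < L - self.primer_right):
                raise ValueError(
                    f"{self.name}: dinucleotide position {p} outside the "
                    f"amplicon interior")
        for rung, positions in self.eccl_tag_positions.items():
            for p in positions:
                if not (self.primer_left <= p < L - self.primer_right):
                    raise ValueError(
                        f"{self.name}: ECCL rung {rung} tag position {p} "
                        f"outside the amplicon interior")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def reference(self) -> np.ndarray:
        return encode_seq(self.sequence)

    @property
    def is_sequence(self) -> str:
        """IS counterpart: reference with dinucleotide substitutions."""
        s = list(self.sequence)
        for p in self.dinucleotide_positions:
            s[p] = IS_SUBSTITUTION[s[p]]
        return "".join(s)

    def eccl_sequence(self, rung: int) -> str:
        """IS sequence of an ECCL rung (rung 1 is the plain IS)."""
        s = list(self.is_sequence)
        for p in self.eccl_tag_positions.get(rung, ()):
            s[p] = IS_SUBSTITUTION[s[p]]
        return "".join(s)

    @property
    def masked_positions(self) -> frozenset[int]:
        """Primer spans plus dinucleotide/tag positions with 1-base flanks."""
        m: set[int] = set(range(self.primer_left))
        m |= set(range(self.length - self.primer_right, self.length))
        special = set(self.dinucleotide_positions)
        for positions in self.eccl_tag_positions.values():
            special |= set(positions)
        for p in special:
            m |= {p - 1, p, p + 1}
        return frozenset(q for q in m if 0 <= q < self.length)

    @property
    def analyzable_positions(self) -> np.ndarray:
        mask = self.masked_positions
        return np.array([p for p in range(self.length) if p not in mask],
                        dtype=np.int64)


@dataclass(frozen=True)
class TargetPanel:
    """The full assay panel: amplicons plus the sample barcode table."""

    amplicons: dict[str, Amplicon]
    barcodes: dict[str, str]  # sample id -> barcode sequence
    barcode_length: int = 10

    def __post_init__(self):
        if len(set(self.barcodes.values())) != len(self.barcodes):
            raise ValueError("duplicate barcodes in the panel barcode table")
        for sid, bc in self.barcodes.items():
            if len(bc) != self.barcode_length:
                raise ValueError(
                    f"barcode for {sid} has length {len(bc)}, "
                    f"expected {self.barcode_length}")

    @property
    def tp53_targets(self) -> tuple[str, ...]:
        return tuple(t for t in TP53_TARGETS if t in self.amplicons)

    @property
    def analyzable_bp(self) -> int:
        """Total analyzable TP53 bases (193 for the standard panel)."""
        return sum(len(self.amplicons[t].analyzable_positions)
                   for t in self.tp53_targets)

    def with_barcodes(self, barcodes: dict[str, str]) -> "TargetPanel":
        return replace(self, barcodes=dict(barcodes))

    # ------------------------------------------------------------------ IO
    def save(self, outdir: str) -> None:
        """Write the panel as FASTA (NT references) + BED spans + barcode TSV.

        BED uses amplicon-local 0-based half-open coordinates with the target
        name in the chrom column; interval names encode the feature kind.
        """
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "panel.fasta"), "w") as fa:
            for amp in self.amplicons.values():
                fa.write(f">{amp.name} {amp.chrom}:{amp.genomic_start}\n")
                fa.write(amp.sequence + "\n")
        with open(os.path.join(outdir, "panel.bed"), "w") as bed:
            for amp in self.amplicons.values():
                L = amp.length
                bed.write(f"{amp.name}\t0\t{amp.primer_left}\tprimer_left\n")
                bed.write(f"{amp.name}\t{L - amp.primer_right}\t{L}"
                          f"\tprimer_right\n")
                for p in amp.dinucleotide_positions:
                    bed.write(f"{amp.name}\t{p}\t{p + 1}\tdinucleotide\n")
                for rung, positions in sorted(amp.eccl_tag_positions.items()):
                    for p in positions:
                        bed.write(f"{amp.name}\t{p}\t{p + 1}"
                                  f"\teccl_tag:{rung}\n")
        with open(os.path.join(outdir, "barcodes.tsv"), "w") as tsv:
            tsv.write("sample_id\tbarcode\n")
            for sid, bc in self.barcodes.items():
                tsv.write(f"{sid}\t{bc}\n")

    @classmethod
    def load(cls, indir: str) -> "TargetPanel":
        from Bio import SeqIO

        seqs: dict[str, tuple[str, str, int]] = {}
        for rec in SeqIO.parse(os.path.join(indir, "panel.fasta"), "fasta"):
            chrom, start = "chrUn", 1
            parts = rec.description.split()
            if len(parts) > 1 and ":" in parts[1]:
                chrom, s = parts[1].split(":")
                start = int(s)
            seqs[rec.id] = (str(rec.seq).upper(), chrom, start)
        feats: dict[str, dict] = {
            name: {"primer_left": 0, "primer_right": 0, "dinuc": [],
                   "tags": {}} for name in seqs}
        with open(os.path.join(indir, "panel.bed")) as bed:
            for line in bed:
                if not line.strip():
                    continue
                name, s, e, kind = line.rstrip("\n").split("\t")[:4]
                s, e = int(s), int(e)
                f = feats[name]
                if kind == "primer_left":
                    f["primer_left"] = e - s
                elif kind == "primer_right":
                    f["primer_right"] = e - s
                elif kind == "dinucleotide":
                    f["dinuc"].extend(range(s, e))
                elif kind.startswith("eccl_tag:"):
                    rung = int(kind.split(":")[1])
                    f["tags"].setdefault(rung, []).extend(range(s, e))
        barcodes: dict[str, str] = {}
        bc_path = os.path.join(indir, "barcodes.tsv")
        if os.path.exists(bc_path):
            with open(bc_path) as tsv:
                next(tsv)
                for line in tsv:
                    sid, bc = line.split()
                    barcodes[sid] = bc
        amplicons = {}
        for name, (seq, chrom, start) in seqs.items():
            f = feats[name]
            amplicons[name] = Amplicon(
                name=name, chrom=chrom, genomic_start=start, sequence=seq,
                primer_left=f["primer_left"], primer_right=f["primer_right"],
                dinucleotide_positions=tuple(sorted(f["dinuc"])),
                eccl_tag_positions={r: tuple(sorted(p))
                                    for r, p in f["tags"].items()})
        bl = len(next(iter(barcodes.values()))) if barcodes else 10
        return cls(amplicons=amplicons, barcodes=barcodes, barcode_length=bl)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode_seq(rng.integers(0, 4, size=length))


def make_barcodes(sample_ids, length: int = 10, min_distance: int = 3,
                  seed: int = 7) -> dict[str, str]:
    """Random barcodes with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    while len(chosen) < len(sample_ids):
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != c).sum()) >= min_distance for c in chosen):
            chosen.append(cand)
    return {sid: decode_seq(c) for sid, c in zip(sample_ids, chosen)}


def mock_panel(sample_ids=(), seed: int = 20530) -> TargetPanel:
    """Build the standard synthetic test panel.

    Reference sequences are synthetic (randomly generated, not hg19), but the
    geometry matches the assay: three TP53 amplicons whose analyzable spans
    sum to 193 bp, IS dinucleotides ~every 50 bases, 20-base primers, and an
    SCGB1A1 amplicon carrying ECCL rung tags.
    """
    rng = np.random.default_rng(seed)
    # amplicon length, dinucleotide pairs -> analyzable 65 + 64 + 64 = 193
    geometry = {
        "TP53.5": (113, ((40, 41), (90, 91)), "chr17", 7578371),
        "TP53.6": (112, ((40, 41), (89, 90)), "chr17", 7578177),
        "TP53.7": (112, ((40, 41), (89, 90)), "chr17", 7577018),
    }
    amplicons: dict[str, Amplicon] = {}
    for name, (L, dinucs, chrom, gstart) in geometry.items():
        amplicons[name] = Amplicon(
            name=name, chrom=chrom, genomic_start=gstart,
            sequence=_random_sequence(rng, L), primer_left=20, primer_right=20,
            dinucleotide_positions=tuple(p for pair in dinucs for p in pair))
    amplicons[SCGB1A1] = Amplicon(
        name=SCGB1A1, chrom="chr11", genomic_start=62170000,
        sequence=_random_sequence(rng, 120), primer_left=20, primer_right=20,
        dinucleotide_positions=(40, 41, 90, 91),
        eccl_tag_positions={2: (55, 56), 3: (60, 61), 4: (65, 66)})
    barcodes = make_barcodes(sample_ids, seed=seed + 1) if sample_ids else {}
    return TargetPanel(amplicons=amplicons, barcodes=barcodes)
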