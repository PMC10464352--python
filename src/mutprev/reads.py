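"""Read demultiplexing, NT/IS classification, and pileup construction.

Reads are full-length amplicon reads prefixed with a 10-base sample barcode.
A read is assigned to a target by its 5' primer, then classified as native
template (NT) or internal standard (IS) by majority vote over the IS
dinucleotide sites: IS if a strict majority of sites carry the IS allele, NT
if a strict majority carry the reference allele, ambiguous otherwise
(ambiguous reads are excluded from pileups but counted).  SCGB1A1 IS reads
are further assigned to an ECCL rung by the rung tag dinucleotides.

Two ingestion paths produce identical pileups: a FASTQ/SAM path that decodes
each read, and a fast path over the simulator's sparse read blocks (shared
template plus explicit per-read error records), which represents exactly the
same reads without materializing their sequences.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np

from .panel import Amplicon, TargetPanel, encode_seq, SCGB1A1

NT, IS, AMBIGUOUS = "NT", "IS", "ambiguous"


@dataclass
class ReadBlock:
    """A set of reads sharing one template sequence, with explicit errors.

    ``err_read``/``err_pos``/``err_alt`` record every substitution error:
    read ``err_read[i]`` (0..n_reads-1) carries base ``err_alt[i]`` at
    amplicon position ``err_pos[i]`` instead of the template base.
    """

    sample_id: str
    target: str
    template: np.ndarray  # int8 (amplicon length,)
    n_reads: int
    err_read: np.ndarray
    err_pos: np.ndarray
    err_alt: np.ndarray
    origin_truth: str = NT  # simulator-side label, never used by classification
    rung_truth: int | None = None
    n_molecules: int = 0  # molecules the reads were duplicated from


ReadSet = list  # list[ReadBlock]


@dataclass
class _Decoder:
    """Per-amplicon decision sites for NT/IS and ECCL rung classification."""

    dinuc_pos: np.ndarray
    ref_allele: np.ndarray
    is_allele: np.ndarray
    min_votes: int
    tag_pos: dict[int, np.ndarray]  # rung -> positions
    tag_allele: dict[int, np.ndarray]
    decision_pos: np.ndarray  # union of all sites above

    @classmethod
    def build(cls, amp: Amplicon, min_votes: int | None = None) -> "_Decoder":
        ref = amp.reference
        is_ref = encode_seq(amp.is_sequence)
        D = np.asarray(amp.dinucleotide_positions, dtype=np.int64)
        tag_pos, tag_allele = {}, {}
        for rung in sorted(amp.eccl_tag_positions):
            tp = np.asarray(amp.eccl_tag_positions[rung], dtype=np.int64)
            tag_pos[rung] = tp
            tag_allele[rung] = encode_seq(amp.eccl_sequence(rung))[tp]
        all_pos = set(D.tolist())
        for tp in tag_pos.values():
            all_pos |= set(tp.tolist())
        return cls(
            dinuc_pos=D, ref_allele=ref[D], is_allele=is_ref[D],
            min_votes=min_votes if min_votes is not None else len(D) // 2 + 1,
            tag_pos=tag_pos, tag_allele=tag_allele,
            decision_pos=np.array(sorted(all_pos), dtype=np.int64))

    def classify(self, read: np.ndarray):
        """Classify one read given its full base array."""
        at = read[self.dinuc_pos]
        nt_votes = int((at == self.ref_allele).sum())
        is_votes = int((at == self.is_allele).sum())
        if is_votes >= self.min_votes and is_votes > nt_votes:
            rung = 1
            for r, tp in self.tag_pos.items():
                if (read[tp] == self.tag_allele[r]).all():
                    rung = r
                    break
            return IS, rung
        if nt_votes >= self.min_votes and nt_votes > is_votes:
            return NT, None
        return AMBIGUOUS, None


@dataclass
class SamplePileup:
    """Per-sample, per-target base counts held separately for NT and IS."""

    sample_id: str
    nt: dict[str, np.ndarray] = field(default_factory=dict)  # (4, L) int64
    is_: dict[str, np.ndarray] = field(default_factory=dict)
    nt_reads: dict[str, int] = field(default_factory=dict)
    is_reads: dict[str, int] = field(default_factory=dict)
    ambiguous: dict[str, int] = field(default_factory=dict)
    eccl_reads: dict[int, int] = field(default_factory=dict)
    unassigned: int = 0

    @classmethod
    def empty(cls, sample_id: str, panel: TargetPanel) -> "SamplePileup":
        sp = cls(sample_id=sample_id)
        for name, amp in panel.amplicons.items():
            sp.nt[name] = np.zeros((4, amp.length), dtype=np.int64)
            sp.is_[name] = np.zeros((4, amp.length), dtype=np.int64)
            sp.nt_reads[name] = 0
            sp.is_reads[name] = 0
            sp.ambiguous[name] = 0
        sp.eccl_reads[1] = 0
        if SCGB1A1 in panel.amplicons:
            for rung in panel.amplicons[SCGB1A1].eccl_tag_positions:
                sp.eccl_reads[rung] = 0
        return sp

    def apply_mask(self, panel: TargetPanel) -> None:
        """Zero out counts at masked positions (primers, dinucleotides +/-1)."""
        for name, amp in panel.amplicons.items():
            masked = sorted(amp.masked_positions)
            self.nt[name][:, masked] = 0
            self.is_[name][:, masked] = 0

    def nt_depth(self, target: str) -> int:
        return self.nt_reads[target]

    def to_tsv(self, path) -> None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            fh.write("sample_id\ttarget\torigin\tpos\tA\tC\tG\tT\n")
            for origin, mats in ((NT, self.nt), (IS, self.is_)):
                for target, mat in mats.items():
                    for pos in range(mat.shape[1]):
                        col = mat[:, pos]
                        if col.sum() == 0:
                            continue
                        fh.write(f"{self.sample_id}\t{target}\t{origin}\t"
                                 f"{pos}\t" + "\t".join(map(str, col)) + "\n")


def _decoders(panel: TargetPanel, min_votes=None) -> dict[str, _Decoder]:
    return {name: _Decoder.build(amp, min_votes)
            for name, amp in panel.amplicons.items()}


def classify_readset(blocks: ReadSet, panel: TargetPanel,
                     min_votes: int | None = None) -> dict[str, SamplePileup]:
    """Classify sparse read blocks into per-sample NT/IS pileups.

    Exact: every read's origin is determined by its own bases at the decision
    sites; reads whose errors touch a decision site are re-examined
    individually, all others inherit their template's classification.
    """
    decoders = _decoders(panel, min_votes)
    out: dict[str, SamplePileup] = {}
    for block in blocks:
        sp = out.get(block.sample_id)
        if sp is None:
            sp = out[block.sample_id] = SamplePileup.empty(
                block.sample_id, panel)
        _accumulate_block(sp, block, panel, decoders[block.target])
    for sp in out.values():
        sp.apply_mask(panel)
    return out


def _accumulate_block(sp: SamplePileup, block: ReadBlock,
                      panel: TargetPanel, dec: _Decoder) -> None:
    t = block.template
    target = block.target
    default_origin, default_rung = dec.classify(t)

    touches = np.isin(block.err_pos, dec.decision_pos)
    affected = np.unique(block.err_read[touches])
    # per-read reclassification for reads with errors at decision sites
    reclass: dict[int, tuple[str, int | None]] = {}
    if affected.size:
        sel = np.isin(block.err_read, affected)
        er, ep, ea = (block.err_read[sel], block.err_pos[sel],
                      block.err_alt[sel])
        order = np.argsort(er, kind="stable")
        er, ep, ea = er[order], ep[order], ea[order]
        bounds = np.searchsorted(er, affected, side="left")
        bounds = np.append(bounds, er.size)
        for i, r in enumerate(affected):
            read = t.copy()
            read[ep[bounds[i]:bounds[i + 1]]] = ea[bounds[i]:bounds[i + 1]]
            reclass[int(r)] = dec.classify(read)

    counts = {NT: 0, IS: 0, AMBIGUOUS: 0}
    counts[default_origin] = block.n_reads - len(reclass)
    rung_counts: dict[int, int] = {}
    if default_origin == IS and target == SCGB1A1:
        rung_counts[default_rung] = block.n_reads - len(reclass)
    for origin, rung in reclass.values():
        counts[origin] += 1
        if origin == IS and target == SCGB1A1:
            rung_counts[rung] = rung_counts.get(rung, 0) + 1

    onehot = np.zeros((4, t.size), dtype=np.int64)
    onehot[t, np.arange(t.size)] = 1
    mats = {NT: sp.nt[target], IS: sp.is_[target]}
    for origin, mat in mats.items():
        if counts[origin]:
            mat += counts[origin] * onehot
    sp.nt_reads[target] += counts[NT]
    sp.is_reads[target] += counts[IS]
    sp.ambiguous[target] += counts[AMBIGUOUS]
    for rung, n in rung_counts.items():
        sp.eccl_reads[rung] = sp.eccl_reads.get(rung, 0) + n

    if block.err_read.size:
        # errors adjust the pileup of whichever origin their read landed in
        origins = np.full(block.err_read.size, default_origin, dtype=object)
        if reclass:
            hit = np.isin(block.err_read, affected)
            origins[hit] = [reclass[int(r)][0] for r in block.err_read[hit]]
        for origin, mat in mats.items():
            sel = origins == origin
            if not sel.any():
                continue
            pos, alt = block.err_pos[sel], block.err_alt[sel]
            np.add.at(mat, (alt, pos), 1)
            np.add.at(mat, (t[pos], pos), -1)


# --------------------------------------------------------------- FASTQ path

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads, panel: TargetPanel, max_mismatch: int = 0):
    """Assign reads to samples by barcode prefix.

    Yields ``(sample_id_or_None, sequence_without_barcode)``; unassigned
    reads come through with sample ``None`` so that callers can count them
    (read conservation: assigned + unassigned = input).
    """
    if not panel.barcodes:
        raise ValueError("panel barcode table is empty")
    bl = panel.barcode_length
    exact = {bc: sid for sid, bc in panel.barcodes.items()}
    for seq in reads:
        bc = seq[:bl]
        sid = exact.get(bc)
        if sid is None and max_mismatch > 0:
            hits = [s for s, b in panel.barcodes.items()
                    if _hamming(bc, b) <= max_mismatch]
            sid = hits[0] if len(hits) == 1 else None
        yield sid, seq[bl:]


def classify_read(seq: str, panel: TargetPanel, min_votes: int | None = None,
                  max_primer_mismatch: int = 2,
                  _decoder_cache: dict | None = None):
    """Classify a single (barcode-stripped) read.

    Returns ``(target, origin, rung, bases)`` where ``bases`` is the int8
    base array over the amplicon, or ``None`` if no primer matches.
    """
    best, best_mm = None, max_primer_mismatch + 1
    for name, amp in panel.amplicons.items():
        if len(seq) < amp.length:
            continue
        mm = _hamming(seq[:amp.primer_left], amp.sequence[:amp.primer_left])
        if mm < best_mm:
            best, best_mm = name, mm
    if best is None:
        return None
    amp = panel.amplicons[best]
    bases = encode_seq(seq[:amp.length])
    if _decoder_cache is not None:
        dec = _decoder_cache.setdefault(best, _Decoder.build(amp, min_votes))
    else:
        dec = _Decoder.build(amp, min_votes)
    origin, rung = dec.classify(bases)
    return best, origin, rung, bases


def pileup_from_fastq(path, panel: TargetPanel, max_mismatch: int = 0,
                      min_votes: int | None = None,
                      min_mean_quality: float | None = None
                      ) -> dict[str, SamplePileup]:
    """Demultiplex + classify a multiplexed FASTQ into per-sample pileups.

    ``min_mean_quality`` applies a mean-Phred filter when real data carries
    informative qualities; simulated FASTQ uses constant qualities and the
    filter is a no-op there.
    """
    from Bio import SeqIO

    pileups: dict[str, SamplePileup] = {
        sid: SamplePileup.empty(sid, panel) for sid in panel.barcodes}
    unassigned = 0
    cache: dict = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = SeqIO.parse(fh, "fastq")

        def seqs():
            nonlocal unassigned
            for rec in records:
                if min_mean_quality is not None:
                    quals = rec.letter_annotations["phred_quality"]
                    if sum(quals) / len(quals) < min_mean_quality:
                        continue
                yield str(rec.seq)

        for sid, seq in demultiplex(seqs(), panel, max_mismatch):
            if sid is None or not _add_read(pileups[sid], seq, panel,
                                            min_votes, cache):
                unassigned += 1
    for sp in pileups.values():
        sp.unassigned = unassigned
        sp.apply_mask(panel)
    return pileups


def _add_read(sp: SamplePileup, seq: str, panel: TargetPanel,
              min_votes, cache) -> bool:
    """Classify one read into a pileup; False if no target primer matched."""
    hit = classify_read(seq, panel, min_votes, _decoder_cache=cache)
    if hit is None:
        return False
    target, origin, rung, bases = hit
    if origin == AMBIGUOUS:
        sp.ambiguous[target] += 1
        return True
    mat = sp.nt[target] if origin == NT else sp.is_[target]
    np.add.at(mat, (bases, np.arange(bases.size)), 1)
    if origin == NT:
        sp.nt_reads[target] += 1
    else:
        sp.is_reads[target] += 1
        if target == SCGB1A1:
            sp.eccl_reads[rung] = sp.eccl_reads.get(rung, 0) + 1
    return True


def pileup_from_sam(path, panel: TargetPanel, sample_id: str,
                    min_votes: int | None = None) -> SamplePileup:
    """Import externally aligned reads (SAM against amplicon references).

    Each alignment must target a panel amplicon by reference name; the read
    is decoded positionally from its alignment start.  Soft-clips and indels
    are not supported (the assay is substitution-only).
    """
    import pysam

    sp = SamplePileup.empty(sample_id, panel)
    cache: dict = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.reference_name not in panel.amplicons:
                sp.unassigned += 1
                continue
            amp = panel.amplicons[aln.reference_name]
            seq = aln.query_sequence
            start = aln.reference_start
            if start != 0 or seq is None or len(seq) < amp.length:
                sp.unassigned += 1
                continue
            if not _add_read(sp, seq, panel, min_votes, cache):
                sp.unassigned += 1
    sp.apply_mask(panel)
    return sp
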