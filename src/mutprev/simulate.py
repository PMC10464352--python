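"""Synthetic amplicon cohort generator with ground truth.

Emulates the statistical structure the pipeline assumes: each subject's
airway specimen carries a Poisson number of clonal TP53 mutations at low VAF
(cases with a higher clone-count mean than controls), every target is
co-amplified with 50,000 synthetic internal-standard (IS) molecules, the
SCGB1A1 IS is a four-rung dilution ladder (ECCL), PCR duplicates each
molecule into a zero-truncated Poisson number of reads, and a shared
technical substitution-error process acts i.i.d. per base per read on NT and
IS reads alike - the premise that makes the IS a valid blank.

Reads are produced as sparse :class:`~mutprev.reads.ReadBlock` records (one
template plus explicit per-read error triplets), which represent exactly the
same reads as a materialized FASTQ; ``write_sample_fastq`` expands them to
literal gzip FASTQ.
"""

from __future__ import annotations

import gzip
import os
import shutil
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import (BASES, SIGNATURE_CLASSES, SCGB1A1, TargetPanel,
                    decode_seq, encode_seq, make_barcodes, mock_panel,
                    substitution_class)
from .reads import ReadBlock


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def uniform_error_matrix(per_substitution_rate: float = 1e-4) -> np.ndarray:
    """4x4 read error matrix with equal probability for every substitution."""
    e = per_substitution_rate
    m = np.full((4, 4), e)
    np.fill_diagonal(m, 1.0 - 3.0 * e)
    return m


def _default_signature_weights() -> dict[str, float]:
    # tobacco (C>A) dominated spectrum with age signatures, as seen in
    # smoking-associated TP53 mutation spectra
    return {"C>A": 0.45, "C>T": 0.30, "T>C": 0.15, "other": 0.10}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_subjects_case: int = 30
    n_subjects_control: int = 29
    molecules_per_target_nt: int = 50_000
    molecules_per_target_is: int = 50_000
    # the assay yields ~26M reads/sample over ~4e5 loaded molecules
    reads_per_molecule_mean: float = 60.0
    error_matrix: np.ndarray = field(
        default_factory=lambda: uniform_error_matrix(1e-4))
    clone_mean_case: float = 159 / 30  # mean true mutation clones per case
    clone_mean_control: float = 33 / 29
    clone_vaf_range: tuple[float, float] = (1e-4, 1e-2)
    signature_weights: dict[str, float] = field(
        default_factory=_default_signature_weights)
    eccl_rungs: tuple[int, ...] = (50_000, 5_000, 500, 50)
    eccl_min_reads: int = 10

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        for name in ("n_subjects_case", "n_subjects_control",
                     "molecules_per_target_nt", "molecules_per_target_is"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.reads_per_molecule_mean <= 0:
            raise ConfigurationError("reads_per_molecule_mean must be > 0")
        E = np.asarray(self.error_matrix, dtype=float)
        if E.shape != (4, 4) or (E < 0).any() or (E > 1).any():
            raise ConfigurationError(
                "error_matrix must be a 4x4 matrix of probabilities")
        if not np.allclose(E.sum(axis=1), 1.0):
            raise ConfigurationError("error_matrix rows must sum to 1")
        for name in ("clone_mean_case", "clone_mean_control"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        lo, hi = self.clone_vaf_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("clone_vaf_range must lie within (0, 1)")
        w = self.signature_weights
        if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1) > 1e-9:
            raise ConfigurationError(
                "signature_weights must be probabilities summing to 1")
        if set(w) - set(SIGNATURE_CLASSES):
            raise ConfigurationError(
                f"signature_weights keys must be among {SIGNATURE_CLASSES}")
        rungs = self.eccl_rungs
        if len(rungs) == 0 or any(r <= 0 for r in rungs):
            raise ConfigurationError("eccl_rungs must be positive counts")
        if list(rungs) != sorted(rungs, reverse=True) or \
                len(set(rungs)) != len(rungs):
            raise ConfigurationError("eccl_rungs must be strictly decreasing")
        if self.eccl_min_reads < 0:
            raise ConfigurationError("eccl_min_reads must be non-negative")

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["error_matrix"] = np.asarray(self.error_matrix).tolist()
        d["clone_vaf_range"] = list(self.clone_vaf_range)
        d["eccl_rungs"] = list(self.eccl_rungs)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "error_matrix" in d:
            d["error_matrix"] = np.asarray(d["error_matrix"], dtype=float)
        if "clone_vaf_range" in d:
            d["clone_vaf_range"] = tuple(d["clone_vaf_range"])
        if "eccl_rungs" in d:
            d["eccl_rungs"] = tuple(d["eccl_rungs"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class TruthMutation:
    target: str
    pos: int  # 0-based amplicon offset
    ref: str
    alt: str
    vaf: float
    sig_class: str


@dataclass
class SubjectTruth:
    subject_id: str
    group: str  # "CA" or "NC"
    mutations: list[TruthMutation]
    nt_molecules: dict[str, int]
    is_molecules: dict[str, int]
    eccl_molecules: dict[int, int]  # rung -> nominal molecules
    read_seed: int = 0


@dataclass
class TruthSet:
    subjects: list[SubjectTruth]

    def by_id(self, subject_id: str) -> SubjectTruth:
        return next(s for s in self.subjects if s.subject_id == subject_id)


@dataclass(frozen=True)
class EcclObservation:
    """One ECCL rung: nominal spiked molecules and observed reads."""

    rung: int
    nominal_molecules: int
    reads: int

    def __post_init__(self):
        if self.nominal_molecules <= 0:
            raise ValueError("nominal_molecules must be > 0")
        if self.reads < 0:
            raise ValueError("reads must be >= 0")


# ------------------------------------------------------------------ cohort

def _candidate_sites(panel: TargetPanel):
    """Analyzable TP53 sites grouped by the substitution classes they admit.

    Returns ``{cls: [(target, pos, ref, alt), ...]}`` covering every
    analyzable (position, alt) pair exactly once.
    """
    sites: dict[str, list[tuple[str, int, str, str]]] = {
        c: [] for c in SIGNATURE_CLASSES}
    for tname in panel.tp53_targets:
        amp = panel.amplicons[tname]
        seq = amp.sequence
        for pos in amp.analyzable_positions:
            ref = seq[pos]
            for alt in BASES:
                if alt == ref:
                    continue
                sites[substitution_class(ref, alt)].append(
                    (tname, int(pos), ref, alt))
    return sites


def simulate_cohort(config: SimulationConfig,
                    panel: TargetPanel | None = None
                    ) -> tuple[pd.DataFrame, TruthSet]:
    """Draw per-subject ground truth for a case-control cohort.

    Deterministic given ``config.seed``.  Returns a subject table (with true
    clone counts and prevalence) and the full :class:`TruthSet`.
    """
    config.validate()
    if panel is None:
        panel = mock_panel()
    rng = np.random.default_rng(config.seed)
    sites = _candidate_sites(panel)
    classes = [c for c in SIGNATURE_CLASSES if config.signature_weights.get(c)]
    weights = np.array([config.signature_weights[c] for c in classes])
    weights = weights / weights.sum()
    lo, hi = config.clone_vaf_range

    subjects: list[SubjectTruth] = []
    rows = []
    groups = ([("CA", config.clone_mean_case)] * config.n_subjects_case +
              [("NC", config.clone_mean_control)] * config.n_subjects_control)
    for i, (group, clone_mean) in enumerate(groups):
        sid = f"{'C' if group == 'CA' else 'N'}{i + 1:03d}"
        n_clones = int(rng.poisson(clone_mean))
        chosen: set[tuple[str, int, str]] = set()
        mutations: list[TruthMutation] = []
        while len(mutations) < n_clones:
            cls = classes[rng.choice(len(classes), p=weights)]
            cands = sites[cls]
            target, pos, ref, alt = cands[rng.integers(len(cands))]
            key = (target, pos, alt)
            if key in chosen:
                continue  # clones are unique (position, alt) pairs
            chosen.add(key)
            vaf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            mutations.append(TruthMutation(target, pos, ref, alt, vaf, cls))
        truth = SubjectTruth(
            subject_id=sid, group=group, mutations=mutations,
            nt_molecules={t: config.molecules_per_target_nt
                          for t in panel.amplicons},
            is_molecules={t: config.molecules_per_target_is
                          for t in panel.amplicons if t != SCGB1A1},
            eccl_molecules={r + 1: n
                            for r, n in enumerate(config.eccl_rungs)},
            read_seed=int(rng.integers(2 ** 31)))
        subjects.append(truth)
        rows.append({"subject_id": sid, "cancer_status": group,
                     "true_clone_count": n_clones,
                     "true_prevalence": n_clones / panel.analyzable_bp})
    return pd.DataFrame(rows), TruthSet(subjects=subjects)


# ------------------------------------------------------------------- reads

def _truncated_poisson(rng: np.random.Generator, mean: float,
                       n: int) -> np.ndarray:
    """n draws from Poisson(mean) conditioned on >= 1 (PCR duplication)."""
    draws = rng.poisson(mean, size=n)
    while True:
        zero = draws == 0
        if not zero.any():
            return draws
        draws[zero] = rng.poisson(mean, size=int(zero.sum()))


def _sample_distinct(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k distinct integers from range(n) without an O(n) permutation."""
    if k >= n:
        return np.arange(n)
    out = np.unique(rng.integers(0, n, size=k))
    while out.size < k:
        extra = rng.integers(0, n, size=k - out.size)
        out = np.unique(np.concatenate([out, extra]))
    return out


def _draw_errors(rng: np.random.Generator, template: np.ndarray,
                 n_reads: int, E: np.ndarray):
    """Sample i.i.d. per-base substitution errors for n_reads copies."""
    err_r, err_p, err_a = [], [], []
    for pos, b in enumerate(template):
        e = 1.0 - E[b, b]
        if e <= 0 or n_reads == 0:
            continue
        k = int(rng.binomial(n_reads, e))
        if k == 0:
            continue
        readix = _sample_distinct(rng, n_reads, k)
        probs = E[b].copy()
        probs[b] = 0.0
        probs /= probs.sum()
        alts = rng.choice(4, size=readix.size, p=probs)
        err_r.append(readix)
        err_p.append(np.full(readix.size, pos, dtype=np.int32))
        err_a.append(alts.astype(np.int8))
    if err_r:
        return (np.concatenate(err_r).astype(np.int64),
                np.concatenate(err_p), np.concatenate(err_a))
    return (np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int32),
            np.zeros(0, dtype=np.int8))


def _make_block(rng, sample_id, target, template, molecules, config,
                origin, rung=None) -> ReadBlock | None:
    if molecules <= 0:
        return None
    dup = _truncated_poisson(rng, config.reads_per_molecule_mean, molecules)
    n_reads = int(dup.sum())
    er, ep, ea = _draw_errors(rng, template, n_reads,
                              np.asarray(config.error_matrix, dtype=float))
    return ReadBlock(sample_id=sample_id, target=target, template=template,
                     n_reads=n_reads, err_read=er, err_pos=ep, err_alt=ea,
                     origin_truth=origin, rung_truth=rung,
                     n_molecules=int(molecules))


def simulate_sample_reads(subject: SubjectTruth, panel: TargetPanel,
                          config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[ReadBlock], list[EcclObservation]]:
    """Simulate one subject's multiplexed reads as sparse read blocks.

    NT molecules carrying each truth clone are Binomial(n_nt, VAF) draws;
    every molecule is duplicated into >=1 reads; technical errors hit NT and
    IS reads with the same per-base matrix.  The returned ECCL observations
    are the true per-rung read counts (the pipeline re-measures them by
    classification).
    """
    if rng is None:
        rng = np.random.default_rng(subject.read_seed)
    for m in subject.mutations:
        if m.target not in panel.amplicons:
            raise ValueError(f"truth mutation target {m.target} not in panel")
        amp = panel.amplicons[m.target]
        if m.pos not in set(amp.analyzable_positions.tolist()):
            raise ValueError(
                f"truth mutation at {m.target}:{m.pos} outside the "
                f"analyzable mask")

    blocks: list[ReadBlock] = []
    eccl: list[EcclObservation] = []
    sid = subject.subject_id
    for tname, amp in panel.amplicons.items():
        ref = amp.reference
        n_nt = subject.nt_molecules.get(tname, 0)
        muts = [m for m in subject.mutations if m.target == tname]
        mutant_counts = [int(rng.binomial(n_nt, m.vaf)) for m in muts]
        total_mut = sum(mutant_counts)
        if total_mut > n_nt:  # VAFs are <=1%, overlap is effectively nil
            mutant_counts = [int(c * n_nt / total_mut) for c in mutant_counts]
            total_mut = sum(mutant_counts)
        b = _make_block(rng, sid, tname, ref, n_nt - total_mut, config, "NT")
        if b:
            blocks.append(b)
        for m, count in zip(muts, mutant_counts):
            tmpl = ref.copy()
            tmpl[m.pos] = BASES.index(m.alt)
            b = _make_block(rng, sid, tname, tmpl, count, config, "NT")
            if b:
                blocks.append(b)
        if tname == SCGB1A1:
            for rung, nominal in subject.eccl_molecules.items():
                tmpl = encode_seq(amp.eccl_sequence(rung))
                b = _make_block(rng, sid, tname, tmpl, nominal, config,
                                "IS", rung=rung)
                if b:
                    blocks.append(b)
                    eccl.append(EcclObservation(rung, nominal, b.n_reads))
        else:
            n_is = subject.is_molecules.get(tname, 0)
            b = _make_block(rng, sid, tname, encode_seq(amp.is_sequence),
                            n_is, config, "IS")
            if b:
                blocks.append(b)
    return blocks, eccl


# ------------------------------------------------------------------- FASTQ

def block_sequences(block: ReadBlock, panel: TargetPanel):
    """Expand a sparse read block into literal read sequences (with barcode)."""
    barcode = panel.barcodes[block.sample_id]
    base = decode_seq(block.template)
    per_read: dict[int, list[tuple[int, int]]] = {}
    for r, p, a in zip(block.err_read, block.err_pos, block.err_alt):
        per_read.setdefault(int(r), []).append((int(p), int(a)))
    for i in range(block.n_reads):
        if i in per_read:
            s = list(base)
            for p, a in per_read[i]:
                s[p] = BASES[a]
            yield barcode + "".join(s)
        else:
            yield barcode + base


def write_fastq(blocks: list[ReadBlock], panel: TargetPanel, path) -> int:
    """Write read blocks as gzip FASTQ (constant Q40 qualities); returns n."""
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for block in blocks:
            for seq in block_sequences(block, panel):
                fh.write(f"@read_{n}\n{seq}\n+\n{'I' * len(seq)}\n")
                n += 1
    return n


# ------------------------------------------------------------- fixture I/O

def packaged_cohort_path() -> str:
    """Path of the packaged 60-subject case-control cohort CSV."""
    return os.path.join(os.path.dirname(__file__), "data",
                        "cohort_table1.csv")


def write_truth_and_fixture(outdir, config: SimulationConfig | None = None,
                            panel: TargetPanel | None = None) -> dict:
    """Simulate a cohort and write FASTQ + truth tables + the cohort fixture.

    Writes ``reads.fastq.gz`` (all subjects multiplexed), ``truth_mutations
    .tsv``, ``truth_subjects.tsv``, ``panel/`` and a copy of the packaged
    cohort CSV; returns the written paths.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    cohort, truth = simulate_cohort(config, panel)
    if panel is None:
        panel = mock_panel()
    panel = panel.with_barcodes(make_barcodes(
        [s.subject_id for s in truth.subjects], seed=config.seed + 101))
    os.makedirs(outdir, exist_ok=True)
    fastq = os.path.join(outdir, "reads.fastq.gz")
    all_blocks: list[ReadBlock] = []
    for subject in truth.subjects:
        blocks, _ = simulate_sample_reads(subject, panel, config)
        all_blocks.extend(blocks)
    write_fastq(all_blocks, panel, fastq)

    mut_path = os.path.join(outdir, "truth_mutations.tsv")
    with open(mut_path, "w") as fh:
        fh.write("subject_id\tgroup\ttarget\tpos\tref\talt\tvaf\tsig_class\n")
        for s in truth.subjects:
            for m in s.mutations:
                fh.write(f"{s.subject_id}\t{s.group}\t{m.target}\t{m.pos}\t"
                         f"{m.ref}\t{m.alt}\t{m.vaf:.6g}\t{m.sig_class}\n")
    subj_path = os.path.join(outdir, "truth_subjects.tsv")
    cohort.to_csv(subj_path, sep="\t", index=False)
    panel_dir = os.path.join(outdir, "panel")
    panel.save(panel_dir)
    fixture = os.path.join(outdir, "cohort_table1.csv")
    shutil.copyfile(packaged_cohort_path(), fixture)
    return {"fastq": fastq, "truth_mutations": mut_path,
            "truth_subjects": subj_path, "panel": panel_dir,
            "cohort_fixture": fixture}
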