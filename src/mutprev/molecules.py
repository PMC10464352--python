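"""Calibrated molecule counting: ECCL evaluation, competitive-template
formulas, molecule-scale down-sampling, and sample QC.

The competitive design co-amplifies each native template (NT) with a known
number of synthetic internal-standard (IS) molecules, so read-count ratios
convert directly into molecule counts.  The SCGB1A1 IS is a dilution ladder
(ECCL, default 50,000 / 5,000 / 500 / 50 molecules): if its lowest rung still
yields reads, the library captured the full 50,000-molecule complexity;
otherwise the captured complexity is scaled down proportionally.  NT pileups
are then thinned to molecule scale so that each retained read represents an
independent input molecule, the independence the downstream Poisson exact
test assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import TargetPanel, SCGB1A1
from .reads import SamplePileup
from .simulate import EcclObservation

DEFAULT_CEILING = 50_000
#: QC floors: minimum calibrator (IS1) reads and minimum molecules per target
DEFAULT_MIN_IS1_READS = 1_000
DEFAULT_MIN_TARGET_MOLECULES = 10_000


class QCFailure(RuntimeError):
    """Raised when a sample cannot be calibrated at all."""


@dataclass
class MoleculeEstimate:
    sample_id: str
    is1_adjusted_molecules: float
    scgb1a1_nt_molecules: float
    nt_molecules: dict[str, float] = field(default_factory=dict)
    qc_pass: bool = True
    qc_reason: str | None = None

    def fail(self, reason: str) -> "MoleculeEstimate":
        self.qc_pass = False
        self.qc_reason = reason if self.qc_reason is None \
            else f"{self.qc_reason}; {reason}"
        return self


def evaluate_eccl(observations: list[EcclObservation], min_reads: int = 10,
                  ceiling: int = DEFAULT_CEILING) -> float:
    """Adjusted IS1 molecule count from the ECCL dilution ladder.

    If the most dilute rung meets ``min_reads``, the full ``ceiling`` was
    captured.  Otherwise the ceiling is scaled down by the ratio of the
    lowest rung's nominal count to the deepest still-passing rung's nominal
    count (a 10-fold ladder loses a factor of 10 per failing rung).

    Raises :class:`QCFailure` if the ladder is empty or no rung passes.
    """
    if not observations:
        raise QCFailure("empty ECCL ladder")
    obs = sorted(observations, key=lambda o: -o.nominal_molecules)
    passing = [o for o in obs if o.reads >= min_reads]
    if not passing:
        raise QCFailure("no ECCL rung reached the minimum read count")
    deepest_passing = min(passing, key=lambda o: o.nominal_molecules)
    lowest = obs[-1]
    return ceiling * lowest.nominal_molecules / deepest_passing.nominal_molecules


def count_scgb1a1_nt_molecules(nt_reads: float, is1_reads: float,
                               is1_adjusted_molecules: float) -> float:
    """SCGB1A1 NT molecules = (NT reads / IS1 reads) x adjusted IS1 molecules."""
    if is1_reads <= 0:
        raise QCFailure("no SCGB1A1 IS1 reads: cannot calibrate")
    return nt_reads / is1_reads * is1_adjusted_molecules


def count_target_nt_molecules(target_nt_reads: float, scgb_nt_reads: float,
                              scgb_nt_molecules: float,
                              formula_literal: bool = False) -> float:
    """Per-target NT molecules from the SCGB1A1-anchored read ratio.

    The dimensionally coherent form is
    ``(target NT reads / SCGB1A1 NT reads) x SCGB1A1 NT molecules``.
    ``formula_literal=True`` instead divides by the molecule count (an
    audit-only variant preserving a typeset ambiguity in the source method).
    """
    if scgb_nt_reads <= 0:
        raise QCFailure("no SCGB1A1 NT reads: cannot calibrate")
    ratio = target_nt_reads / scgb_nt_reads
    if formula_literal:
        if scgb_nt_molecules <= 0:
            raise QCFailure("zero SCGB1A1 NT molecules in literal formula")
        return ratio / scgb_nt_molecules
    return ratio * scgb_nt_molecules


def estimate_molecules(sp: SamplePileup, panel: TargetPanel,
                       eccl_rungs: tuple[int, ...] = (50_000, 5_000, 500, 50),
                       eccl_min_reads: int = 10,
                       ceiling: int | None = None,
                       formula_literal: bool = False) -> MoleculeEstimate:
    """Full calibration of one sample from its classified pileup.

    ``eccl_rungs`` are the nominal molecule counts spiked per ladder rung
    (rung 1 first); the adjustment ceiling defaults to the top rung.
    """
    est = MoleculeEstimate(sample_id=sp.sample_id,
                           is1_adjusted_molecules=float("nan"),
                           scgb1a1_nt_molecules=float("nan"))
    nominals = _rung_nominals(panel, tuple(eccl_rungs))
    obs = [EcclObservation(r, nominals[r], sp.eccl_reads.get(r, 0))
           for r in sorted(nominals)]
    try:
        est.is1_adjusted_molecules = evaluate_eccl(
            obs, min_reads=eccl_min_reads,
            ceiling=eccl_rungs[0] if ceiling is None else ceiling)
        est.scgb1a1_nt_molecules = count_scgb1a1_nt_molecules(
            sp.nt_reads[SCGB1A1], sp.eccl_reads.get(1, 0),
            est.is1_adjusted_molecules)
        for target in panel.tp53_targets:
            est.nt_molecules[target] = count_target_nt_molecules(
                sp.nt_reads[target], sp.nt_reads[SCGB1A1],
                est.scgb1a1_nt_molecules, formula_literal=formula_literal)
    except QCFailure as exc:
        return est.fail(str(exc))
    return est


def _rung_nominals(panel: TargetPanel,
                   rungs: tuple[int, ...] = (50_000, 5_000, 500, 50)
                   ) -> dict[int, int]:
    """Nominal molecules per ECCL rung (rung 1 = the undiluted IS1)."""
    amp = panel.amplicons[SCGB1A1]
    n_rungs = 1 + len(amp.eccl_tag_positions)
    return {i + 1: rungs[i] for i in range(min(n_rungs, len(rungs)))}


def downsample_to_molecules(sp: SamplePileup, estimate: MoleculeEstimate,
                            seed: int) -> SamplePileup:
    """Thin NT pileups to molecule scale by per-position hypergeometric draws.

    At each position the four base counts are reduced, without replacement,
    to a total equal to the (rounded) molecule estimate; expected allele
    fractions are preserved and the draw is reproducible from ``seed``.
    Positions whose depth is already at or below the target are untouched.
    """
    rng = np.random.default_rng(seed)
    out = SamplePileup(
        sample_id=sp.sample_id,
        nt={t: m.copy() for t, m in sp.nt.items()},
        is_={t: m.copy() for t, m in sp.is_.items()},
        nt_reads=dict(sp.nt_reads), is_reads=dict(sp.is_reads),
        ambiguous=dict(sp.ambiguous), eccl_reads=dict(sp.eccl_reads),
        unassigned=sp.unassigned)
    for target, molecules in estimate.nt_molecules.items():
        if not np.isfinite(molecules):
            continue
        m = int(round(molecules))
        mat = out.nt[target]
        for pos in range(mat.shape[1]):
            col = mat[:, pos]
            depth = int(col.sum())
            if depth <= m or depth == 0:
                continue
            mat[:, pos] = rng.multivariate_hypergeometric(col, m)
    return out


def qc_sample(sp: SamplePileup, estimate: MoleculeEstimate,
              panel: TargetPanel,
              min_is1_reads: int = DEFAULT_MIN_IS1_READS,
              min_target_molecules: int = DEFAULT_MIN_TARGET_MOLECULES
              ) -> MoleculeEstimate:
    """Apply sample-level QC floors; failure reasons are recorded, and a
    failing sample is excluded from cohort statistics downstream."""
    if not estimate.qc_pass:
        return estimate
    if sp.eccl_reads.get(1, 0) < min_is1_reads:
        return estimate.fail(
            f"calibrator reads below floor "
            f"({sp.eccl_reads.get(1, 0)} < {min_is1_reads})")
    for target in panel.tp53_targets:
        mol = estimate.nt_molecules.get(target, float("nan"))
        if not np.isfinite(mol) or mol < min_target_molecules:
            return estimate.fail(
                f"{target} molecule estimate {mol:.0f} below floor "
                f"{min_target_molecules}")
    return estimate
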