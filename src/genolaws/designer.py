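"""Constrained sequence design under the independence model.

Given a target GC content s and purine content r, the per-base sampling
probabilities are the independence-factorization products

    P(A) = (1-s)·r,  P(T) = (1-s)·(1-r),  P(G) = s·r,  P(C) = s·(1-r).

Two sampling modes:

``iid``
    each position drawn independently from these probabilities — the
    minimal generative model consistent with marginal base probabilities;
``exact``
    base counts fixed by largest-remainder (Hamilton) apportionment of
    length × probabilities, then shuffled, so the achieved composition is
    as close to the target as integer counts allow.

A seed is mandatory; identical spec → byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from genolaws.composition import count_bases, profile_from_counts
from genolaws.fasta_io import GenomeRecord
from genolaws.laws import estimate_profile

__all__ = ["DesignSpec", "DesignVerification", "design_sequence", "verify_design"]

_BASES = "ATGC"
_BASE_BYTES = np.frombuffer(b"ATGC", dtype=np.uint8)


@dataclass(frozen=True)
class DesignSpec:
    """Design targets: GC content, purine content, length, seed, mode."""

    target_s: float
    target_r: float
    length: int
    seed: int
    mode: str = "iid"

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_s <= 1.0:
            raise ValueError(f"target_s={self.target_s} outside [0, 1]")
        if not 0.0 <= self.target_r <= 1.0:
            raise ValueError(f"target_r={self.target_r} outside [0, 1]")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.mode not in ("iid", "exact"):
            raise ValueError(f"mode must be 'iid' or 'exact', got {self.mode!r}")

    @property
    def probabilities(self) -> tuple[float, float, float, float]:
        """Per-base probabilities (A, T, G, C) from the factorization."""
        est = estimate_profile(self.target_s, self.target_r)
        return est.p_a, est.p_t, est.p_g, est.p_c


def _apportion(length: int, probs: tuple[float, float, float, float]) -> list[int]:
    """Largest-remainder apportionment of ``length`` positions.

    Floors first, then assigns leftovers by descending fractional
    remainder; ties break deterministically in base order A, T, G, C.
    """
    quotas = [length * p for p in probs]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = length - sum(counts)
    order = sorted(range(4), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def design_sequence(spec: DesignSpec) -> GenomeRecord:
    """Generate a sequence meeting the design spec.

    The FASTA-ready record header encodes the spec and the PRNG used
    (numpy PCG64) so the output is reproducible from the header alone.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.array(spec.probabilities, dtype=float)
    if spec.mode == "iid":
        idx = rng.choice(4, size=spec.length, p=probs / probs.sum())
    else:
        counts = _apportion(spec.length, spec.probabilities)
        idx = np.repeat(np.arange(4), counts)
        rng.shuffle(idx)
    sequence = _BASE_BYTES[idx].tobytes().decode("ascii")
    description = (
        f"designed s={spec.target_s} r={spec.target_r} length={spec.length} "
        f"seed={spec.seed} mode={spec.mode} prng=numpy-PCG64 genolaws=0.1.0"
    )
    record_id = f"design_s{spec.target_s}_r{spec.target_r}_L{spec.length}_seed{spec.seed}_{spec.mode}"
    return GenomeRecord(id=record_id, sequence=sequence, description=description)


@dataclass(frozen=True)
class DesignVerification:
    achieved_s: float
    achieved_r: float
    deviation_s: float
    deviation_r: float
    tolerance_s: float
    tolerance_r: float
    passed: bool

    def as_dict(self) -> dict:
        return {
            "achieved_s": self.achieved_s,
            "achieved_r": self.achieved_r,
            "deviation_s": self.deviation_s,
            "deviation_r": self.deviation_r,
            "tolerance_s": self.tolerance_s,
            "tolerance_r": self.tolerance_r,
            "passed": self.passed,
        }


def _iid_tolerance(p: float, length: int) -> float:
    # 4 binomial standard errors; a false alarm rate of ~1e-4 per target.
    return 4.0 * np.sqrt(max(p * (1.0 - p), 0.0) / length)


def verify_design(record: GenomeRecord, spec: DesignSpec) -> DesignVerification:
    """Compare a sequence's achieved GC/purine content with its targets.

    Exact mode must land within the apportionment bound 2/length on each
    target; iid mode is allowed 4 binomial standard errors.
    """
    profile = profile_from_counts(count_bases(record.sequence))
    dev_s = abs(profile.p_s - spec.target_s)
    dev_r = abs(profile.p_r - spec.target_r)
    if spec.mode == "exact":
        tol_s = tol_r = 2.0 / spec.length
    else:
        tol_s = _iid_tolerance(spec.target_s, spec.length)
        tol_r = _iid_tolerance(spec.target_r, spec.length)
    return DesignVerification(
        achieved_s=profile.p_s,
        achieved_r=profile.p_r,
        deviation_s=float(dev_s),
        deviation_r=float(dev_r),
        tolerance_s=float(tol_s),
        tolerance_r=float(tol_r),
        passed=bool(dev_s <= tol_s and dev_r <= tol_r),
    )
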