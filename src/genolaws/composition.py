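"""Base counting and the composition algebra.

A genome's composition is summarized by eight proportions over the base
alphabet Ω = {A, T, G, C}: the four base proportions plus the contents of
the derived subsets S = G∪C (strong / GC), W = A∪T = Sᶜ (weak / AT),
R = A∪G (purine) and Y = T∪C = Rᶜ (pyrimidine).  Proportions are computed
on the strand as given; ambiguity codes are tallied separately and excluded
from the denominator, so ``p_a + p_t + p_g + p_c == 1`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "IUPAC_ALPHABET",
    "BaseCounts",
    "CompositionProfile",
    "count_bases",
    "aggregate_counts",
    "profile_from_counts",
    "reverse_complement",
]

#: Uppercase IUPAC nucleotide one-letter codes accepted after normalization.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: IUPAC codes that do not resolve to a single base.
AMBIGUITY_CODES = IUPAC_ALPHABET - frozenset("ACGT")

_COMPLEMENT_TABLE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class BaseCounts:
    """Integer tallies of a sequence set.

    ``n_ambiguous`` counts IUPAC codes outside {A, C, G, T}; ``n_total`` is
    derived so the tallies always partition the sequence length.
    """

    n_a: int = 0
    n_t: int = 0
    n_g: int = 0
    n_c: int = 0
    n_ambiguous: int = 0

    def __post_init__(self) -> None:
        for name in ("n_a", "n_t", "n_g", "n_c", "n_ambiguous"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def n_unambiguous(self) -> int:
        return self.n_a + self.n_t + self.n_g + self.n_c

    @property
    def n_total(self) -> int:
        return self.n_unambiguous + self.n_ambiguous

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        if not isinstance(other, BaseCounts):
            return NotImplemented
        return BaseCounts(
            self.n_a + other.n_a,
            self.n_t + other.n_t,
            self.n_g + other.n_g,
            self.n_c + other.n_c,
            self.n_ambiguous + other.n_ambiguous,
        )


@dataclass(frozen=True)
class CompositionProfile:
    """The eight composition proportions of one genome.

    Base proportions are over unambiguous bases only; ``ambiguous_fraction``
    (relative to the full sequence length) is carried so callers can judge
    how much of the assembly was excluded.  ``n_counted`` is the unambiguous
    base count, or ``None`` for profiles reconstructed from proportions
    alone (e.g. from a published composition table).
    """

    p_a: float
    p_t: float
    p_g: float
    p_c: float
    ambiguous_fraction: float = 0.0
    n_counted: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_a", "p_t", "p_g", "p_c"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        total = self.p_a + self.p_t + self.p_g + self.p_c
        if abs(total - 1.0) > 5e-3:
            raise ValueError(f"base proportions sum to {total:.4f}, expected 1")
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ValueError("ambiguous_fraction must lie in [0, 1)")
        if self.n_counted is not None and self.n_counted < 1:
            raise ValueError("n_counted must be positive when given")

    # Derived contents. S∪W and R∪Y each partition Ω, so the pairs sum to 1
    # exactly up to floating error in the base proportions.
    @property
    def p_s(self) -> float:
        """GC content, S = G∪C."""
        return self.p_g + self.p_c

    @property
    def p_w(self) -> float:
        """AT content, W = A∪T = Sᶜ."""
        return self.p_a + self.p_t

    @property
    def p_r(self) -> float:
        """Purine content, R = A∪G."""
        return self.p_a + self.p_g

    @property
    def p_y(self) -> float:
        """Pyrimidine content, Y = T∪C = Rᶜ."""
        return self.p_t + self.p_c

    def as_dict(self, decimals: int | None = None) -> dict:
        """Flat mapping of all fields; proportions optionally rounded."""

        def f(x: float) -> float:
            return round(x, decimals) if decimals is not None else x

        return {
            "p_a": f(self.p_a),
            "p_t": f(self.p_t),
            "p_g": f(self.p_g),
            "p_c": f(self.p_c),
            "p_s": f(self.p_s),
            "p_w": f(self.p_w),
            "p_r": f(self.p_r),
            "p_y": f(self.p_y),
            "ambiguous_fraction": f(self.ambiguous_fraction),
            "n_counted": self.n_counted,
        }


def count_bases(sequence: str) -> BaseCounts:
    """Tally A/T/G/C and ambiguity codes in a normalized sequence.

    The sequence must already be normalized (uppercase IUPAC, no gaps);
    :func:`genolaws.fasta_io.read_fasta` emits sequences in that form.
    """
    if not sequence:
        raise ValueError("cannot count bases of an empty sequence")
    n_a = sequence.count("A")
    n_t = sequence.count("T")
    n_g = sequence.count("G")
    n_c = sequence.count("C")
    n_ambiguous = len(sequence) - (n_a + n_t + n_g + n_c)
    bad = set(sequence) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return BaseCounts(n_a, n_t, n_g, n_c, n_ambiguous)


def aggregate_counts(counts_list) -> BaseCounts:
    """Fieldwise sum of per-record tallies into one genome-level tally."""
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("cannot aggregate an empty collection of counts")
    total = BaseCounts()
    for c in counts_list:
        total = total + c
    return total


def profile_from_counts(counts: BaseCounts) -> CompositionProfile:
    """Convert tallies to proportions over unambiguous bases.

    Raises
    ------
    ValueError
        If the tally contains no unambiguous base (e.g. an all-N record).
    """
    n = counts.n_unambiguous
    if n < 1:
        raise ValueError("no unambiguous bases to profile")
    return CompositionProfile(
        p_a=counts.n_a / n,
        p_t=counts.n_t / n,
        p_g=counts.n_g / n,
        p_c=counts.n_c / n,
        ambiguous_fraction=counts.n_ambiguous / counts.n_total,
        n_counted=n,
    )


def reverse_complement(sequence: str) -> str:
    """Reverse complement with full IUPAC ambiguity support.

    R↔Y, K↔M, B↔V, D↔H; S, W and N are self-complementary.
    """
    bad = set(sequence) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"cannot complement non-IUPAC characters: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT_TABLE)[::-1]
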