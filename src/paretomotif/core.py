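"""Core data model: sequence sets, candidate motifs, profiles and objectives.

A candidate motif is a width ``w`` together with one start position per
sequence (one-occurrence-per-sequence model).  Extracting the ``N`` sites,
tallying a 4 x w position frequency matrix and scoring it gives the two
maximized objectives:

* consensus similarity  ``sum_j f_max(j) / (N * w)``  in (0.25, 1], where
  ``f_max(j)`` is the largest base count in column ``j``;
* normalized length     ``w / w_max``  in (0, 1].

Fitness vectors are compared by Pareto dominance under maximization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

WIDTH_MIN = 4
WIDTH_MAX = 20

# byte -> base code lookup; 255 marks an invalid character
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i

_AMBIGUITY = set("RYSWKMBDHVN")


class ValidationError(ValueError):
    """Raised when sequences, candidates or sites violate model invariants."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValidationError(f"invalid character {bad!r} in sequence")
    return arr


def decode_sequence(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


class SequenceSet:
    """Ordered set of N unaligned DNA sequences over {A, C, G, T}.

    Parameters
    ----------
    records
        Iterable of ``(identifier, sequence)`` pairs.
    strict
        If True (default) any character outside A/C/G/T is rejected.  If
        False, lowercase letters are uppercased first and only IUPAC
        ambiguity codes (N, R, Y, ...) are rejected.
    """

    def __init__(self, records: Iterable[tuple[str, str]], *, strict: bool = True):
        self.ids: list[str] = []
        self.sequences: list[str] = []
        seen: set[str] = set()
        for ident, seq in records:
            if ident in seen:
                raise ValidationError(f"duplicate sequence id {ident!r}")
            seen.add(ident)
            if not strict:
                up = seq.upper()
                amb = _AMBIGUITY.intersection(up)
                if amb:
                    raise ValidationError(
                        f"record {ident!r} contains ambiguity code(s) {sorted(amb)}"
                    )
                seq = up
            self.ids.append(ident)
            self.sequences.append(seq)
        if len(self.sequences) < 2:
            raise ValidationError("a sequence set needs at least 2 sequences")
        try:
            self.encoded: list[np.ndarray] = [encode_sequence(s) for s in self.sequences]
        except ValidationError as exc:
            raise ValidationError(f"{exc} (strict alphabet is A/C/G/T)") from None
        self.lengths = np.array([len(s) for s in self.sequences], dtype=np.int64)
        if int(self.lengths.min()) < WIDTH_MIN:
            raise ValidationError(
                f"shortest sequence ({int(self.lengths.min())} bp) is below the "
                f"minimum motif width {WIDTH_MIN}"
            )

    @property
    def N(self) -> int:
        return len(self.sequences)

    @property
    def min_length(self) -> int:
        return int(self.lengths.min())

    def __len__(self) -> int:
        return self.N

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))


@dataclass(frozen=True)
class Candidate:
    """One GA individual: motif width plus a 0-based start per sequence."""

    width: int
    starts: tuple[int, ...]

    def validate(self, seqs: SequenceSet, *, width_min: int = WIDTH_MIN,
                 width_max: int = WIDTH_MAX) -> None:
        w_hi = min(width_max, seqs.min_length)
        if not width_min <= self.width <= w_hi:
            raise ValidationError(
                f"width {self.width} outside [{width_min}, {w_hi}]"
            )
        if len(self.starts) != seqs.N:
            raise ValidationError(
                f"candidate has {len(self.starts)} starts for {seqs.N} sequences"
            )
        for i, p in enumerate(self.starts):
            hi = int(seqs.lengths[i]) - self.width
            if not 0 <= p <= hi:
                raise ValidationError(
                    f"start {p} out of range [0, {hi}] for sequence index {i}"
                )


@dataclass(frozen=True)
class SiteSet:
    """The N extracted sites, one per sequence, all of the same width."""

    sites: tuple[str, ...]

    @property
    def width(self) -> int:
        return len(self.sites[0])

    @property
    def N(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class ProfileMatrix:
    """4 x w count matrix over aligned sites; rows in fixed A, C, G, T order."""

    counts: np.ndarray  # shape (4, width), integer

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValidationError("profile counts must have shape (4, width)")
        if (c < 0).any():
            raise ValidationError("profile counts must be non-negative")
        sums = c.sum(axis=0)
        if sums.size and not (sums == sums[0]).all():
            raise ValidationError("profile columns must all sum to the same N")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def N(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class FitnessVector:
    """The two maximized objectives of a candidate motif."""

    similarity: float
    norm_length: float

    def as_array(self) -> np.ndarray:
        return np.array([self.similarity, self.norm_length])


class Dominance(enum.Enum):
    U_SUPERIOR = "u_superior"
    V_SUPERIOR = "v_superior"
    NON_INFERIOR = "non_inferior"


@dataclass(frozen=True)
class SiteAnnotation:
    """A located motif occurrence; serialized as one 6-column BED line.

    Coordinates are 0-based half-open, as in BED.  Only the forward strand
    is modelled.
    """

    seq_id: str
    start: int
    end: int
    name: str = "motif"
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start or self.start < 0:
            raise ValidationError(
                f"malformed interval [{self.start}, {self.end}) on {self.seq_id!r}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# operations


def extract_sites(candidate: Candidate, seqs: SequenceSet) -> SiteSet:
    """Extract the candidate's site from each sequence.

    Site ``i`` is the substring of sequence ``i`` at
    ``[starts[i], starts[i] + width)``.
    """
    candidate.validate(seqs)
    w = candidate.width
    return SiteSet(tuple(
        seqs.sequences[i][p:p + w] for i, p in enumerate(candidate.starts)
    ))


def site_matrix(width: int, starts: Sequence[int], seqs: SequenceSet) -> np.ndarray:
    """Encoded (N, width) site matrix; fast path used by the engine."""
    out = np.empty((seqs.N, width), dtype=np.uint8)
    for i, p in enumerate(starts):
        out[i] = seqs.encoded[i][p:p + width]
    return out


def profile_counts(sites: np.ndarray) -> np.ndarray:
    """Per-column base tallies of an encoded (N, width) site matrix."""
    counts = np.empty((4, sites.shape[1]), dtype=np.int64)
    for b in range(4):
        counts[b] = (sites == b).sum(axis=0)
    return counts


def build_profile(sites: SiteSet | Sequence[str]) -> ProfileMatrix:
    """Count the frequency of each base at each position of the site set."""
    strings = sites.sites if isinstance(sites, SiteSet) else tuple(sites)
    widths = {len(s) for s in strings}
    if len(widths) != 1:
        raise ValidationError(f"ragged site lengths {sorted(widths)}")
    mat = np.stack([encode_sequence(s) for s in strings])
    return ProfileMatrix(profile_counts(mat))


def consensus_string(profile: ProfileMatrix) -> str:
    """Per-column most frequent base; ties broken by fixed order A < C < G < T."""
    # np.argmax returns the first maximal row, i.e. the A<C<G<T tie rule
    return "".join(ALPHABET[i] for i in np.argmax(profile.counts, axis=0))


def similarity_score(profile: ProfileMatrix, N: int | None = None,
                     width: int | None = None) -> float:
    """Normalized consensus similarity: sum of column maxima over N * width.

    Equals 1.0 iff all N sites are identical; bounded below by 0.25 (the
    per-column maximum is at least N/4).
    """
    N = profile.N if N is None else N
    width = profile.width if width is None else width
    if N <= 0 or width <= 0:
        raise ValidationError("similarity_score needs N >= 1 and width >= 1")
    return float(profile.counts.max(axis=0).sum()) / (N * width)


def normalized_length(width: int, width_max: int = WIDTH_MAX,
                      width_min: int = WIDTH_MIN) -> float:
    """Motif width divided by the maximum allowed width."""
    if not width_min <= width <= width_max:
        raise ValidationError(
            f"width {width} outside [{width_min}, {width_max}]"
        )
    return width / width_max


def fitness(candidate: Candidate, seqs: SequenceSet,
            width_max: int = WIDTH_MAX) -> FitnessVector:
    """Evaluate the two objectives of a candidate. Pure and deterministic."""
    candidate.validate(seqs, width_max=max(width_max, candidate.width))
    mat = site_matrix(candidate.width, candidate.starts, seqs)
    counts = profile_counts(mat)
    sim = float(counts.max(axis=0).sum()) / (seqs.N * candidate.width)
    return FitnessVector(sim, normalized_length(candidate.width, width_max))


def compare(u: FitnessVector | Sequence[float],
            v: FitnessVector | Sequence[float]) -> Dominance:
    """Pareto-compare two fitness vectors under maximization.

    ``u`` is superior iff it is at least as good in every component and
    strictly better in at least one; symmetrically for ``v``.  Equal vectors
    and objective trade-offs are mutually non-inferior.
    """
    ua = u.as_array() if isinstance(u, FitnessVector) else np.asarray(u, dtype=float)
    va = v.as_array() if isinstance(v, FitnessVector) else np.asarray(v, dtype=float)
    if (ua >= va).all() and (ua > va).any():
        return Dominance.U_SUPERIOR
    if (va >= ua).all() and (va > ua).any():
        return Dominance.V_SUPERIOR
    return Dominance.NON_INFERIOR
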