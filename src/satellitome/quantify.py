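"""Per-family abundance and Kimura divergence from read libraries.

Reads are masked against the catalogue: each read (and, for reads
straddling array boundaries, each read half) is aligned to every variant
consensus treated as circular (tiled) on both strands; segments at
``min_identity`` or better over at least ``min_len`` bp are assigned to
the best-scoring variant. Abundance is the percentage of sampled read
nucleotides assigned to a family; divergence is the Kimura two-parameter
distance of assigned segments to the consensus, pooled across segments.

A k-mer prefilter (exact match of a short word against the catalogue on
either strand) skips reads with no chance of matching; at the default
word size reads within ~20% divergence of a variant essentially always
carry an intact word, while beyond that a small fraction may be skipped
— disable the prefilter (``prefilter_k=None``) for exact masking of
highly divergent material.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import edlib
import numpy as np
import pandas as pd

from ._seq import decode, decode_rows, encode, kmer_codes, revcomp
from .catalog import SatFamily
from .errors import DivergenceUndefinedError, InvalidParameterError

PURINES = frozenset("AG")

MASK_MIN_IDENTITY = 0.70
MASK_MIN_LEN = 30
PREFILTER_K = 13


@dataclass
class AbundanceRecord:
    family: str
    genome: str
    abundance_percent: float
    divergence_percent: Optional[float]
    reads_sampled: int
    assigned_reads: int = 0


@dataclass
class Assignment:
    read_id: int
    family: str
    variant: int
    aligned_len: int
    transitions: int
    transversions: int
    sites: int

    @property
    def mismatch_fraction(self) -> float:
        return (self.transitions + self.transversions) / max(self.sites, 1)


def _tile(seq: str, span: int) -> str:
    """Tile a monomer so any window of length ``span`` fits linearly."""
    reps = max(2, -(-(span + 2 * len(seq)) // len(seq)))
    return seq * reps


_IS_PURINE = np.array([True, False, True, False])  # A, C, G, T


def _max_scoring_span(diff: np.ndarray, mismatch_penalty: float = 1.2) -> tuple[int, int]:
    """Maximal-scoring contiguous span of a match/mismatch vector
    (match +1, mismatch -penalty); ungapped local alignment by Kadane.
    The default penalty trims only stretches denser than ~45% mismatch —
    random background, not divergent family sequence."""
    best = cur = 0.0
    best_lo = best_hi = cur_lo = 0
    for i, is_mm in enumerate(diff):
        cur += -mismatch_penalty if is_mm else 1.0
        if cur <= 0:
            cur = 0.0
            cur_lo = i + 1
        elif cur > best:
            best = cur
            best_lo, best_hi = cur_lo, i + 1
    return best_lo, best_hi


def _count_substitutions(query: str, target_codes: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, aligned sites) for a read segment.

    The segment is slid ungapped over the tiled consensus and scored at
    the minimum-mismatch offset — exact for a pure substitution process
    (gapped alignments absorb substitution clusters into indels and bias
    divergence downward). Falls back to the gapped edlib path when no
    ungapped placement reaches half identity.
    """
    q = encode(query)
    n = target_codes.size - q.size + 1
    if n >= 1:
        windows = np.lib.stride_tricks.sliding_window_view(target_codes, q.size)
        mism = (windows != q[None, :]).sum(axis=1)
        best = int(np.argmin(mism))
        if mism[best] <= 0.5 * q.size:
            w = windows[best]
            diff = w != q
            # local trim: drop near-random read ends (reads straddling an
            # array boundary carry a background tail that would otherwise
            # inflate the divergence)
            lo, hi = _max_scoring_span(diff)
            if hi - lo >= 15:
                d = diff[lo:hi]
                ts = int((d & (_IS_PURINE[q[lo:hi]] == _IS_PURINE[w[lo:hi]])).sum())
                return ts, int(d.sum()) - ts, hi - lo
    # indel-containing (or pathological) segment: gapped path, gap columns excluded
    target = decode(target_codes)
    res = edlib.align(query, target, mode="HW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    ts = tv = sites = 0
    for qc, tc in zip(nice["query_aligned"], nice["target_aligned"]):
        if qc == "-" or tc == "-":
            continue
        sites += 1
        if qc != tc:
            if (qc in PURINES) == (tc in PURINES):
                ts += 1
            else:
                tv += 1
    return ts, tv, sites


class Masker:
    """Aligns reads against a catalogue of variant consensuses."""

    def __init__(
        self,
        families: Sequence[Union[SatFamily, tuple[str, str]]],
        min_identity: float = MASK_MIN_IDENTITY,
        min_len: int = MASK_MIN_LEN,
        prefilter_k: Optional[int] = PREFILTER_K,
        max_span: int = 160,
    ):
        if not families:
            raise InvalidParameterError("catalogue must be non-empty")
        self.min_identity = min_identity
        self.min_len = min_len
        self.prefilter_k = prefilter_k
        self.max_span = max_span
        self.variants: list[tuple[str, int, str]] = []  # (family, variant idx, seq)
        for fam in families:
            if isinstance(fam, SatFamily):
                name = fam.name or fam.consensus
                for k, v in enumerate(fam.variants):
                    self.variants.append((name, k, v))
            else:
                name, seq = fam
                self.variants.append((name, 0, seq))
        self._tiled = [(_tile(v, max_span)) for (_, _, v) in self.variants]
        self._tiled_codes = [encode(t) for t in self._tiled]
        self._kmer_set = self._build_kmer_set() if prefilter_k else None

    def _build_kmer_set(self) -> np.ndarray:
        k = self.prefilter_k
        mats = []
        for _, _, v in self.variants:
            tiled = v * max(2, -(-(k + len(v)) // len(v)))
            mats.append(kmer_codes(encode(tiled)[None, :], k).ravel())
        return np.unique(np.concatenate(mats))

    def candidate_mask(self, reads: np.ndarray) -> np.ndarray:
        """Boolean mask of reads sharing at least one catalogue k-mer."""
        if self._kmer_set is None:
            return np.ones(reads.shape[0], dtype=bool)
        k = self.prefilter_k
        out = np.zeros(reads.shape[0], dtype=bool)
        chunk = max(1, 50_000_000 // max(reads.shape[1] * 8, 1))
        for lo in range(0, reads.shape[0], chunk):
            sub = reads[lo : lo + chunk]
            codes = kmer_codes(sub, k)
            hit = np.isin(codes, self._kmer_set, assume_unique=False)
            out[lo : lo + chunk] = hit.any(axis=1)
        return out

    def _best_segment(self, seq: str) -> Optional[tuple[int, float, str]]:
        """Best (variant index, identity, query segment) for a read string."""
        segments = [seq]
        half = len(seq) // 2
        if half >= self.min_len:
            segments += [seq[:half], seq[half:]]
        best = None
        for seg_i, segment in enumerate(segments):
            k_allow = int((1 - self.min_identity) * len(segment))
            queries = (segment, revcomp(segment))
            for vi, tiled in enumerate(self._tiled):
                for q in queries:
                    d = edlib.align(q, tiled, mode="HW", task="distance", k=k_allow)["editDistance"]
                    if d < 0:
                        continue
                    ident = 1.0 - d / len(segment)
                    if ident >= self.min_identity and (best is None or ident > best[1]):
                        best = (vi, ident, q)
            if seg_i == 0 and best is not None:
                break  # whole read matched; halves can only be sub-segments
        return best

    def match_read(self, seq: str) -> Optional[tuple[int, float, str]]:
        return self._best_segment(seq)

    def matches(self, reads: np.ndarray) -> np.ndarray:
        """Boolean mask: read aligns to any variant at the thresholds."""
        cand = self.candidate_mask(reads)
        out = np.zeros(reads.shape[0], dtype=bool)
        idx = np.flatnonzero(cand)
        seqs = decode_rows(reads[idx]) if idx.size else []
        for pos, seq in zip(idx, seqs):
            out[pos] = self._best_segment(seq) is not None
        return out

    def assign(self, reads: np.ndarray, count_substitutions: bool = True) -> list[Assignment]:
        """Mask reads and collect per-segment substitution counts.

        ``count_substitutions=False`` skips the base-level alignment walk
        (transitions/transversions reported as 0, sites as 0) — an
        abundance-only fast path.
        """
        cand = self.candidate_mask(reads)
        idx = np.flatnonzero(cand)
        seqs = decode_rows(reads[idx]) if idx.size else []
        out: list[Assignment] = []
        for pos, seq in zip(idx, seqs):
            hit = self._best_segment(seq)
            if hit is None:
                continue
            vi, ident, query = hit
            fam, var, _ = self.variants[vi]
            if count_substitutions:
                ts, tv, sites = _count_substitutions(query, self._tiled_codes[vi])
            else:
                ts = tv = sites = 0
            out.append(
                Assignment(
                    read_id=int(pos),
                    family=fam,
                    variant=var,
                    aligned_len=len(query),
                    transitions=ts,
                    transversions=tv,
                    sites=sites,
                )
            )
        return out


def mask_reads(
    reads: np.ndarray,
    catalogue: Sequence[Union[SatFamily, tuple[str, str]]],
    min_identity: float = MASK_MIN_IDENTITY,
    min_len: int = MASK_MIN_LEN,
    prefilter_k: Optional[int] = PREFILTER_K,
    count_substitutions: bool = True,
) -> list[Assignment]:
    """Assign reads to catalogue variants (see module docstring)."""
    masker = Masker(catalogue, min_identity=min_identity, min_len=min_len, prefilter_k=prefilter_k)
    return masker.assign(np.atleast_2d(reads), count_substitutions=count_substitutions)


def kimura_divergence(transitions: int, transversions: int, sites: int) -> float:
    """Kimura two-parameter distance (%) from substitution counts.

    With P = transitions/sites and Q = transversions/sites the distance is
    -1/2 ln((1-2P-Q) sqrt(1-2Q)); raises when the logarithm argument is
    non-positive (saturation).
    """
    if sites <= 0:
        raise InvalidParameterError("sites must be positive")
    if transitions + transversions > sites:
        raise InvalidParameterError("more substitutions than sites")
    p = transitions / sites
    q = transversions / sites
    arg = (1 - 2 * p - q) * math.sqrt(max(1 - 2 * q, 0.0))
    if arg <= 0:
        raise DivergenceUndefinedError(f"saturated substitution fractions P={p:.3f} Q={q:.3f}")
    return 100.0 * (-0.5 * math.log(arg))


def abundance(
    assignments: Sequence[Assignment],
    total_nt: int,
    genome: str = "",
    reads_sampled: int = 0,
    per_variant: bool = False,
) -> pd.DataFrame:
    """Roll assignments up to per-family (or per-variant) abundance records.

    ``abundance_percent`` uses total sampled nucleotides as denominator;
    divergence is the pooled Kimura distance of all assigned segments
    (NaN when saturated or no segment was assigned).
    """
    if total_nt <= 0:
        raise InvalidParameterError("total_nt must be positive")
    keys = (lambda a: (a.family, a.variant)) if per_variant else (lambda a: a.family)
    groups: dict = {}
    for a in assignments:
        groups.setdefault(keys(a), []).append(a)
    rows = []
    for key, group_ in sorted(groups.items(), key=lambda kv: str(kv[0])):
        nt = sum(a.aligned_len for a in group_)
        ts = sum(a.transitions for a in group_)
        tv = sum(a.transversions for a in group_)
        sites = sum(a.sites for a in group_)
        try:
            div = kimura_divergence(ts, tv, sites) if sites else float("nan")
        except DivergenceUndefinedError:
            div = float("nan")
        row = {
            "family": key[0] if per_variant else key,
            "abundance_percent": 100.0 * nt / total_nt,
            "divergence_percent": div,
            "assigned_reads": len(group_),
            "assigned_nt": nt,
            "genome": genome,
            "reads_sampled": reads_sampled,
        }
        if per_variant:
            row["variant"] = key[1]
        rows.append(row)
    cols = ["family", "abundance_percent", "divergence_percent", "assigned_reads", "assigned_nt", "genome", "reads_sampled"]
    if per_variant:
        cols.insert(1, "variant")
    return pd.DataFrame(rows, columns=cols)


def quantify_library(
    library,
    catalogue: Sequence[Union[SatFamily, tuple[str, str]]],
    genome: str = "",
    max_pairs: int = 10_000_000,
    min_identity: float = MASK_MIN_IDENTITY,
    min_len: int = MASK_MIN_LEN,
    prefilter_k: Optional[int] = PREFILTER_K,
    seed: int = 0,
    count_substitutions: bool = True,
) -> pd.DataFrame:
    """Mask up to ``max_pairs`` pairs of a library and return the abundance
    table, including zero rows for catalogue families without any hit."""
    n = min(max_pairs, library.n_pairs)
    if n < library.n_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(library.n_pairs, size=n, replace=False)
        library = library.subset(np.sort(idx))
    reads = library.reads()
    assignments = mask_reads(
        reads, catalogue, min_identity, min_len, prefilter_k, count_substitutions=count_substitutions
    )
    table = abundance(assignments, total_nt=reads.shape[0] * reads.shape[1], genome=genome, reads_sampled=reads.shape[0])
    names = []
    for fam in catalogue:
        names.append((fam.name or fam.consensus) if isinstance(fam, SatFamily) else fam[0])
    missing = [n_ for n_ in names if n_ not in set(table["family"])]
    if missing:
        zeros = pd.DataFrame(
            {
                "family": missing,
                "abundance_percent": 0.0,
                "divergence_percent": float("nan"),
                "assigned_reads": 0,
                "assigned_nt": 0,
                "genome": genome,
                "reads_sampled": reads.shape[0],
            }
        )
        table = pd.concat([table, zeros], ignore_index=True)
    return table.sort_values("family", ignore_index=True)
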