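"""0B vs 1B abundance comparison and B-chromosome association inference.

Adding one B chromosome of length fraction ``f`` of the haploid A
complement to a diploid genome dilutes every satellite absent from the B
by at most (f/2)/(1+f/2) — about 4% when f = 0.08. Families whose 1B/0B
abundance ratio rises (positive log2) are B-enrichment candidates; those
whose relative decrease exceeds the dilution bound cannot be explained by
B absence alone (the usual reading: between-individual variation in
satellite abundance). Putatively B-specific families are verified by
scanning 0B reads for dimers/multimers of the monomer and by a targeted
reclustering of monomer-homologous read pairs from each library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from ._seq import decode_rows, revcomp
from .catalog import rotational_identity
from .discovery import (
    MIN_PERIOD,
    MAX_PERIOD,
    SUBTRACT_MIN_COV,
    SUBTRACT_MIN_IDENTITY,
    TANDEM_SCORE,
    cluster_reads,
    detect_tandem,
)
from .errors import InfeasibleScanError, InvalidParameterError, UndefinedRatioError
from .quantify import Masker
from .simgen import ReadLibrary

B_FRACTION_DEFAULT = 0.08
RECLUSTER_PAIRS = 2500

CLASS_ENRICHED = "B-enriched candidate"
CLASS_WITHIN = "decrease-within-threshold"
CLASS_BEYOND = "decrease-beyond-threshold"
CLASS_UNDEFINED = "undefined"


def log2_ratio(a1: float, a0: float) -> float:
    """log2 of the 1B/0B abundance quotient."""
    if a0 <= 0 or a1 <= 0:
        raise UndefinedRatioError(f"log2 ratio undefined for a1={a1}, a0={a0}")
    return math.log2(a1 / a0)


def expected_max_decrease(f: float) -> float:
    """Maximum relative abundance decrease of a satellite absent from the B.

    One B of length f x (haploid A complement) added to a diploid genome
    grows the genome by a factor 1 + f/2, so the relative loss is
    (f/2)/(1 + f/2).
    """
    if f < 0:
        raise InvalidParameterError(f"negative B fraction f={f}")
    if f >= 1:
        raise InvalidParameterError(f"B fraction f={f} must be < 1")
    return (f / 2) / (1 + f / 2)


@dataclass
class BComparisonRecord:
    family: str
    a0: float
    a1: float
    f: float
    log2_ratio: Optional[float] = None
    expected_max_decrease: float = 0.0
    classification: str = CLASS_UNDEFINED

    def __post_init__(self) -> None:
        self.expected_max_decrease = expected_max_decrease(self.f)
        if self.a0 > 0 and self.a1 > 0:
            self.log2_ratio = log2_ratio(self.a1, self.a0)


def classify(records: Sequence[BComparisonRecord]) -> list[BComparisonRecord]:
    """Attach the B-association classification to each record.

    Positive log2 -> B-enrichment candidate; otherwise the relative
    decrease 1 - a1/a0 is compared against the dilution bound.
    """
    for rec in records:
        if rec.log2_ratio is None:
            rec.classification = CLASS_UNDEFINED
            continue
        if rec.log2_ratio > 0:
            rec.classification = CLASS_ENRICHED
        else:
            decrease = 1.0 - rec.a1 / rec.a0
            rec.classification = CLASS_WITHIN if decrease <= rec.expected_max_decrease else CLASS_BEYOND
    return list(records)


def compare_abundances(
    table_0b: pd.DataFrame,
    table_1b: pd.DataFrame,
    f: float = B_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Join per-family 0B/1B abundance tables into a classified comparison."""
    a0 = dict(zip(table_0b["family"], table_0b["abundance_percent"]))
    a1 = dict(zip(table_1b["family"], table_1b["abundance_percent"]))
    records = [
        BComparisonRecord(family=name, a0=a0.get(name, 0.0), a1=a1.get(name, 0.0), f=f)
        for name in sorted(set(a0) | set(a1))
    ]
    classify(records)
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "a0": r.a0,
                "a1": r.a1,
                "log2_ratio": r.log2_ratio,
                "expected_max_decrease": r.expected_max_decrease,
                "classification": r.classification,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# tandem-structure verification


def multimer_scan(
    reads: np.ndarray,
    monomer: str,
    min_copies: int = 2,
    min_identity: float = 0.80,
) -> int:
    """Count reads containing >= min_copies consecutive monomer copies.

    A read qualifies when a full monomer occurrence (either strand, any
    phase) is flanked by an adjacent occurrence within the identity
    threshold — i.e. the monomer is locally tandem, not a dispersed single
    copy.
    """
    reads = np.atleast_2d(reads)
    read_len = reads.shape[1]
    if min_copies < 1:
        raise InvalidParameterError("min_copies must be >= 1")
    if len(monomer) * min_copies > read_len:
        raise InfeasibleScanError(
            f"monomer of {len(monomer)} bp x {min_copies} copies exceeds read length {read_len}"
        )
    k_allow = int((1 - min_identity) * len(monomer))
    count = 0
    for seq in decode_rows(reads):
        if _has_tandem(seq, monomer, min_copies, k_allow, min_identity):
            count += 1
    return count


def _has_tandem(seq: str, monomer: str, min_copies: int, k_allow: int, min_identity: float) -> bool:
    m = len(monomer)
    for probe in (monomer, revcomp(monomer)):
        res = edlib.align(probe, seq, mode="HW", task="locations", k=k_allow)
        if res["editDistance"] < 0:
            continue
        if min_copies == 1:
            return True
        for start, end in res["locations"][:4]:
            copies = 1
            # extend rightwards copy by copy
            pos = end + 1
            while pos + m <= len(seq) and copies < min_copies:
                window = seq[pos : pos + m]
                d = edlib.align(probe, window, mode="NW", task="distance", k=k_allow)["editDistance"]
                if d < 0:
                    break
                copies += 1
                pos += m
            # and leftwards
            pos = start
            while pos - m >= 0 and copies < min_copies:
                window = seq[pos - m : pos]
                d = edlib.align(probe, window, mode="NW", task="distance", k=k_allow)["editDistance"]
                if d < 0:
                    break
                copies += 1
                pos -= m
            if copies >= min_copies:
                return True
    return False


@dataclass
class ReclusterReport:
    genome: str
    n_selected_pairs: int
    tandem_detected: bool
    period: Optional[int] = None
    consensus: Optional[str] = None


def targeted_recluster(
    library_0b: ReadLibrary,
    library_1b: ReadLibrary,
    monomer: str,
    n: int = RECLUSTER_PAIRS,
    min_identity: float = SUBTRACT_MIN_IDENTITY,
    min_cov: float = SUBTRACT_MIN_COV,
    match_identity: float = 70.0,
) -> dict[str, ReclusterReport]:
    """Recluster monomer-homologous read pairs from each library separately.

    Selects up to ``n`` pairs per library where either mate matches the
    monomer (same homology thresholds as read subtraction), reruns
    clustering + tandem detection on the selection, and reports whether a
    tandem monomer homologous to the query was recovered. Zero homologous
    reads is reported as absence, not an error.
    """
    reports = {}
    for genome, lib in (("0B", library_0b), ("1B", library_1b)):
        masker = Masker(
            [("query", monomer)],
            min_identity=min_identity,
            min_len=int(min_cov * lib.read_len),
        )
        hit = masker.matches(lib.r1) | masker.matches(lib.r2)
        idx = np.flatnonzero(hit)[:n]
        if idx.size == 0:
            reports[genome] = ReclusterReport(genome=genome, n_selected_pairs=0, tandem_detected=False)
            continue
        selection = lib.subset(idx)
        clusters = cluster_reads(selection.reads(), min_cluster_size=min(10, 2 * idx.size))
        detected = False
        period = None
        consensus = None
        for cluster in clusters[:10]:
            mono = detect_tandem(
                cluster,
                min_period=MIN_PERIOD,
                max_period=MAX_PERIOD,
                score_threshold=TANDEM_SCORE,
            )
            if mono is None:
                continue
            if rotational_identity(mono.consensus, monomer) >= match_identity:
                detected = True
                period = mono.period
                consensus = mono.consensus
                break
        reports[genome] = ReclusterReport(
            genome=genome,
            n_selected_pairs=int(idx.size),
            tandem_detected=detected,
            period=period,
            consensus=consensus,
        )
    return reports
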