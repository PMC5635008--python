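"""Statistics over FISH-derived satellite location tables.

Satellites are scored per species and chromosome as clustered (c,
FISH-visible clusters), non-clustered (nc, genomically present but
cytologically invisible) or telomeric (t). On B chromosomes each cluster
is located by arm (p short, q long) and region (pe pericentromeric, i
interstitial, t terminal, d distal). Because a metacentric B that arose as
an isochromosome has two identical arms, the symmetry of satellite
locations across the two arms carries a signal of B age: the symmetry
index (SI) of a B chromosome is the mean, over its non-centromeric
satellites, of an indicator that the satellite occupies matching regions
on both arms. Terminal and distal both denote the far end of an arm and
are treated as one region class when comparing arms.

The test battery (Shapiro-Wilk, Spearman, Mann-Whitney, Levene, Fisher
exact) reproduces the descriptive comparisons usual in satellitome
papers: repeat-unit-length differences between clustered and
non-clustered satellites, correlation of length with A+T content, and
sharing of clustered satellites between species on A vs B chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sstats

from .errors import InvalidParameterError, UndefinedCorrelationError

ARM_CODES = {"pe", "i", "t", "d"}
ARMS = {"p", "q"}
# terminal and distal are one positional class for arm comparison
_END_MERGE = {"t": "end", "d": "end", "i": "i"}

EXACT_MW_LIMIT = 10_000


# ---------------------------------------------------------------------------
# location records


@dataclass
class LocationRecord:
    """FISH distribution of one satellite on one chromosome (class)."""

    satellite: str
    species: str
    chromosome: str  # "A" or a named B chromosome (e.g. BpM)
    pattern: str  # c | nc | t
    regions: dict[str, set] = field(default_factory=dict)  # arm -> codes; "pe" arm-neutral

    def __post_init__(self) -> None:
        if self.pattern not in {"c", "nc", "t"}:
            raise InvalidParameterError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "nc" and any(self.regions.values()):
            raise InvalidParameterError("non-clustered satellite cannot carry regions")
        for arm, codes in self.regions.items():
            if arm not in ARMS | {"pe"}:
                raise InvalidParameterError(f"unknown arm {arm!r}")
            bad = set(codes) - ARM_CODES
            if bad:
                raise InvalidParameterError(f"unknown region codes {bad}")

    @property
    def has_arm_clusters(self) -> bool:
        return bool(self.regions.get("p") or self.regions.get("q"))

    def arm_set(self, arm: str) -> frozenset:
        return frozenset(_END_MERGE.get(c, c) for c in self.regions.get(arm, ()) if c != "pe")

    @property
    def is_symmetric(self) -> Optional[bool]:
        """Arms match (pericentromeric signal ignored); None if pe-only."""
        if not self.has_arm_clusters:
            return None
        return self.arm_set("p") == self.arm_set("q")


def parse_regions(text: str) -> dict[str, set]:
    """Parse a region string like ``pe;p:i;p:t;q:i;q:t``."""
    regions: dict[str, set] = {}
    text = (text or "").strip()
    if not text or text == "-":
        return regions
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if token == "pe":
            regions.setdefault("pe", set()).add("pe")
            continue
        if ":" not in token:
            raise InvalidParameterError(f"malformed region token {token!r}")
        arm, code = (part.strip() for part in token.split(":", 1))
        if code == "pe":
            regions.setdefault("pe", set()).add("pe")
            continue
        regions.setdefault(arm, set()).add(code)
    return regions


def read_location_table(source) -> list[LocationRecord]:
    """Read a location TSV (satellite, species, chromosome, pattern, regions)."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t", dtype=str)
    records = []
    for _, row in df.iterrows():
        records.append(
            LocationRecord(
                satellite=row["satellite"],
                species=row["species"],
                chromosome=row["chromosome"],
                pattern=row["pattern"],
                regions=parse_regions(row.get("regions", "") if isinstance(row.get("regions"), str) else ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# symmetry index


@dataclass
class SymmetryRecord:
    b_name: str
    n_clusters: int
    n_noncentromeric: int
    n_symmetric: int
    si: Optional[float]


def symmetry_index(records: Sequence[LocationRecord]) -> SymmetryRecord:
    """Symmetry index of one B chromosome.

    Satellites with only pericentromeric clusters are excluded (the
    centromere is arm-neutral); the telomeric satellite (pattern t) is not
    scored. SI is undefined (None) without non-centromeric satellites.
    """
    names = {r.chromosome for r in records}
    if len(names) != 1:
        raise InvalidParameterError(f"records span several chromosomes: {sorted(names)}")
    scored = [r for r in records if r.pattern == "c"]
    flags = [r.is_symmetric for r in scored if r.is_symmetric is not None]
    n_sym = sum(flags)
    si = n_sym / len(flags) if flags else None
    return SymmetryRecord(
        b_name=names.pop(),
        n_clusters=len(scored),
        n_noncentromeric=len(flags),
        n_symmetric=n_sym,
        si=si,
    )


# ---------------------------------------------------------------------------
# test battery


@dataclass
class StatResult:
    name: str
    value: float
    p_value: Optional[float]
    aux: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise InvalidParameterError(f"p-value {self.p_value} outside [0,1]")


def _exact_mw_distribution(combined: np.ndarray, n_x: int) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of 2*U_x over equally likely group assignments.

    Dynamic programme over tie groups of the sorted pooled sample; handles
    midrank ties exactly. Returns (support of 2U values, probabilities).
    """
    values, counts = np.unique(combined, return_counts=True)
    n_total = combined.size
    n_y = n_total - n_x
    max2u = 2 * n_x * n_y
    # dp[x, u2] = number of ways to place x x-elements among processed
    # groups accumulating 2*U_x = u2
    dp = np.zeros((n_x + 1, max2u + 1))
    dp[0, 0] = 1.0
    before = 0  # elements in earlier groups
    from math import comb

    for g_size in counts:
        new = np.zeros_like(dp)
        for xg in range(0, int(g_size) + 1):
            w = comb(int(g_size), xg)
            if w == 0:
                continue
            for x_before in range(0, n_x - xg + 1):
                row = dp[x_before]
                if not row.any():
                    continue
                y_before = before - x_before
                yg = int(g_size) - xg
                shift = xg * (2 * y_before + yg)
                if shift == 0:
                    new[x_before + xg] += w * row
                else:
                    new[x_before + xg, shift:] += w * row[: max2u + 1 - shift]
        dp = new
        before += int(g_size)
    dist = dp[n_x]
    total = dist.sum()
    support = np.arange(max2u + 1)
    mask = dist > 0
    return support[mask], dist[mask] / total


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney test reporting U = min(U_x, U_y).

    Exact P (dynamic programme over tie groups) when n*m <= 10,000;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    u_x = float(ranks[:n].sum() - n * (n + 1) / 2)
    u_y = n * m - u_x
    u = min(u_x, u_y)
    if n * m <= EXACT_MW_LIMIT:
        support, probs = _exact_mw_distribution(combined, n)
        center = n * m  # of 2U
        dev = abs(2 * u_x - center)
        p = float(probs[np.abs(support - center) >= dev - 1e-9].sum())
        method = "exact"
    else:
        res = sstats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "asymptotic"
    return StatResult(
        name="mann-whitney",
        value=u,
        p_value=min(p, 1.0),
        aux={"U1": u_x, "U2": u_y, "n": n, "m": m, "method": method},
    )


def fisher_exact_2x2(table, alternative: str = "two-sided") -> StatResult:
    """Fisher exact test on a 2x2 table.

    Two-sided P sums hypergeometric probabilities of all same-margin
    tables no more probable than the observed one (with 1e-7 relative
    slack); one-sided alternatives give the plain tail.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise InvalidParameterError("need a 2x2 table of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InvalidParameterError("all margins must be positive")
    odds, p = sstats.fisher_exact(arr, alternative=alternative)
    return StatResult(
        name="fisher-exact",
        value=float(odds),
        p_value=float(p),
        aux={"table": arr.tolist(), "alternative": alternative},
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with t-statistic and two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UndefinedCorrelationError("constant input")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        t = float("inf") if r > 0 else float("-inf")
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * float(sstats.t.sf(abs(t), df=n - 2))
    return StatResult(name="spearman", value=r, p_value=p, aux={"t": float(t), "df": n - 2})


def levene(x: Sequence[float], y: Sequence[float], center: str = "mean") -> StatResult:
    """Two-group Levene test of equal variances (mean-centred classic form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("need >= 2 observations per group")
    if np.unique(np.concatenate([x, y])).size == 1:
        raise InvalidParameterError("degenerate input: all values equal")
    f, p = sstats.levene(x, y, center=center)
    df = (1, x.size + y.size - 2)
    return StatResult(name="levene", value=float(f), p_value=float(p), aux={"df": df, "center": center})


def shapiro_wilk(x: Sequence[float]) -> StatResult:
    """Shapiro-Wilk normality test (Royston approximation)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise InvalidParameterError(f"sample size {x.size} outside 3..5000")
    w, p = sstats.shapiro(x)
    return StatResult(name="shapiro-wilk", value=float(w), p_value=float(p), aux={"n": int(x.size)})


# ---------------------------------------------------------------------------
# satellitome summaries


def summarize_rul(families: pd.DataFrame, patterns: Sequence[LocationRecord]) -> dict:
    """Per-pattern repeat-unit-length summaries for one reference species.

    ``families`` needs columns name and rul; ``patterns`` are the
    reference-species A-chromosome records. The telomeric satellite
    (pattern t) is kept out of the clustered/non-clustered dichotomy.
    Variances use the n-1 denominator; single-element groups report None.
    """
    rul = dict(zip(families["name"], families["rul"]))
    groups: dict[str, list[float]] = {"c": [], "nc": [], "t": []}
    for rec in patterns:
        if rec.satellite not in rul:
            raise InvalidParameterError(f"no RUL for {rec.satellite}")
        groups[rec.pattern].append(float(rul[rec.satellite]))

    def describe(vals: list[float]) -> dict:
        if not vals:
            return {"n": 0, "median": None, "variance": None, "min": None, "max": None}
        arr = np.asarray(vals)
        return {
            "n": int(arr.size),
            "median": float(np.median(arr)),
            "variance": float(np.var(arr, ddof=1)) if arr.size > 1 else None,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    all_rul = np.asarray(list(families["rul"]), dtype=float)
    return {
        "clustered": describe(groups["c"]),
        "non_clustered": describe(groups["nc"]),
        "telomeric": describe(groups["t"]),
        "n_scored": sum(len(v) for v in groups.values()),
        "satellitome_median_rul": float(np.median(all_rul)),
        "n_rul_below_100": int((all_rul < 100).sum()),
    }


def statistics_report(
    families: pd.DataFrame,
    patterns: Sequence[LocationRecord],
    b_locations: Sequence[LocationRecord],
    a_patterns: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """The full test battery over a satellitome and its location tables.

    Returns one row per statistic (name, value, p, detail); suitable for
    TSV export or a plain-text summary via :func:`format_report`.
    """
    rul = dict(zip(families["name"], families["rul"]))
    clustered = [float(rul[r.satellite]) for r in patterns if r.pattern == "c"]
    nc = [float(rul[r.satellite]) for r in patterns if r.pattern == "nc"]
    rows = []

    def add(name, value, p, detail=""):
        rows.append({"statistic": name, "value": value, "p_value": p, "detail": detail})

    summary = summarize_rul(families, patterns)
    add("median RUL (satellitome)", summary["satellitome_median_rul"], None,
        f"n={len(families)}, {summary['n_rul_below_100']} families under 100 bp")
    add("median RUL (clustered)", summary["clustered"]["median"], None, f"n={summary['clustered']['n']}")
    add("median RUL (non-clustered)", summary["non_clustered"]["median"], None, f"n={summary['non_clustered']['n']}")
    add("RUL variance (clustered)", summary["clustered"]["variance"], None, "sample variance")
    add("RUL variance (non-clustered)", summary["non_clustered"]["variance"], None, "sample variance")

    if clustered and nc:
        mw = mann_whitney(clustered, nc)
        add("Mann-Whitney U, RUL c vs nc", mw.value, mw.p_value, mw.aux["method"])
        lv = levene(clustered, nc)
        add("Levene F, RUL c vs nc", lv.value, lv.p_value, f"df={lv.aux['df']}")

    for col in ("rul", "at_percent", "abundance_0b", "divergence_0b"):
        if col in families.columns:
            sw = shapiro_wilk(families[col].astype(float))
            add(f"Shapiro-Wilk W ({col})", sw.value, sw.p_value, "")
    if "at_percent" in families.columns:
        sp = spearman(families["rul"].astype(float), families["at_percent"].astype(float))
        add("Spearman r_S, RUL vs A+T", sp.value, sp.p_value, f"t={sp.aux['t']:.2f}, df={sp.aux['df']}")

    for b in sorted({r.chromosome for r in b_locations}):
        rec = symmetry_index([r for r in b_locations if r.chromosome == b])
        add(f"symmetry index ({b})", rec.si, None,
            f"{rec.n_symmetric}/{rec.n_noncentromeric} non-centromeric satellites symmetric")

    if a_patterns is not None:
        table = shared_cluster_table(a_patterns, b_locations)
        fe = fisher_exact_2x2(table, alternative="greater")
        add("Fisher exact, shared clusters A vs B", fe.value, fe.p_value,
            f"table={table.tolist()}, upper tail")
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`statistics_report` output."""
    lines = ["Satellitome statistics", "=" * 22]
    for _, row in report.iterrows():
        val = "NA" if row["value"] is None else f"{row['value']:.4g}"
        p = "" if row["p_value"] is None or pd.isna(row["p_value"]) else f"  P = {row['p_value']:.4g}"
        detail = f"  [{row['detail']}]" if row["detail"] else ""
        lines.append(f"{row['statistic']}: {val}{p}{detail}")
    return "\n".join(lines) + "\n"


def shared_cluster_table(
    a_patterns: pd.DataFrame,
    b_locations: Sequence[LocationRecord],
    reference_species: str = "A. paranae",
) -> np.ndarray:
    """2x2 sharing table for clustered satellites on A vs B chromosomes.

    Row 1: satellites clustered on reference-species A chromosomes —
    shared (clustered in >= 1 other species) vs not. Row 2: satellites
    visualized on any B chromosome — shared by Bs of >= 2 species vs
    B-private. The telomeric satellite is excluded throughout.
    """
    species_cols = [c for c in a_patterns.columns if c != "satellite"]
    if reference_species not in species_cols:
        raise InvalidParameterError(f"{reference_species!r} not among {species_cols}")
    others = [c for c in species_cols if c != reference_species]
    a_clustered = a_patterns[a_patterns[reference_species] == "c"]
    shared_a = (a_clustered[others] == "c").any(axis=1)
    b_sat: dict[str, set] = {}
    for rec in b_locations:
        if rec.pattern == "c":
            b_sat.setdefault(rec.satellite, set()).add(rec.chromosome)
    shared_b = sum(1 for chroms in b_sat.values() if len(chroms) >= 2)
    return np.array(
        [
            [int(shared_a.sum()), int((~shared_a).sum())],
            [shared_b, len(b_sat) - shared_b],
        ]
    )
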