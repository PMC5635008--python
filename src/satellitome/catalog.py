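"""Grouping mined monomers into variants, families and superfamilies.

Satellite monomers are defined only up to rotation and strand, so all
homology here is *rotational* identity: the best global-alignment identity
over every rotation of one sequence and of its reverse complement. Nested
single-linkage grouping at >=95% / >=80% / >=50% identity yields sequence
variants, families and superfamilies; families are then named
``<Prefix>Sat<NN>-<RUL>`` in order of decreasing abundance in the
B-lacking genome, with a ``-tel`` suffix for the vertebrate telomeric
repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np

from ._seq import at_fraction, canonical_rotation, revcomp, rotate
from .errors import InvalidAlphabetError, InvalidParameterError

TELOMERE_MONOMER = "TTAGGG"

VARIANT_IDENTITY = 95.0
FAMILY_IDENTITY = 80.0
SUPERFAMILY_IDENTITY = 50.0


@dataclass
class MinedMonomer:
    """A consensus monomer mined from a read cluster."""

    consensus: str  # canonical rotation
    period: int
    support: int = 1
    iteration: int = 0
    cluster_index: int = -1

    def __post_init__(self) -> None:
        self.consensus = canonical_rotation(self.consensus)
        if self.period != len(self.consensus):
            self.period = len(self.consensus)


@dataclass
class SatFamily:
    """A catalogued satellite DNA family.

    ``consensus`` is the most abundant variant; ``rul`` its length; ``v``
    the number of distinct sequence variants (>=95% identity chains).
    """

    consensus: str
    variants: list[str]
    variant_support: list[int]
    rank: Optional[int] = None
    name: Optional[str] = None
    superfamily_id: Optional[int] = None

    @property
    def rul(self) -> int:
        return len(self.consensus)

    @property
    def at_percent(self) -> float:
        return at_content(self.consensus)

    @property
    def v(self) -> int:
        return len(self.variants)

    @property
    def support(self) -> int:
        return int(sum(self.variant_support))


@dataclass
class Superfamily:
    id: int
    member_ranks: list[int] = field(default_factory=list)
    member_indices: list[int] = field(default_factory=list)
    defining_identity: float = 0.0


# ---------------------------------------------------------------------------
# identity


def at_content(consensus: str) -> float:
    """A+T percentage of a consensus sequence."""
    if not consensus:
        raise InvalidAlphabetError("empty sequence")
    if any(c not in "ACGT" for c in consensus):
        raise InvalidAlphabetError(f"non-ACGT character in {consensus!r}")
    return 100.0 * at_fraction(consensus)


def _alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity (%): matches / alignment columns.

    Gap columns count as mismatches. Uses an edlib-optimal (minimum edit
    distance) path.
    """
    res = edlib.align(b, a, mode="NW", task="path")
    dist = res["editDistance"]
    cigar = res["cigar"]
    cols = sum(int(n) for n, _ in _cigar_ops(cigar))
    return 100.0 * (cols - dist) / cols


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def rotational_identity(a: str, b: str) -> float:
    """Best identity (%) of ``a`` vs every rotation of ``b`` on both strands."""
    if not a or not b:
        raise InvalidParameterError("rotational identity of empty sequence")
    best_candidates: list[str] = []
    best_dist = None
    for strand in (b, revcomp(b)):
        for k in range(len(strand)):
            rot = rotate(strand, k)
            d = edlib.align(rot, a, mode="NW", task="distance")["editDistance"]
            if best_dist is None or d < best_dist:
                best_dist = d
                best_candidates = [rot]
            elif d <= best_dist + 1:
                best_candidates.append(rot)
    # edlib minimises edit distance, not matches/columns; re-score the
    # near-optimal rotations with full paths.
    return max(_alignment_identity(a, rot) for rot in best_candidates[:8])


def _upper_bound_identity(a: str, b: str) -> float:
    """Cheap upper bound on rotational identity from the length difference."""
    la, lb = len(a), len(b)
    return 100.0 * min(la, lb) / max(la, lb)


def chance_identity_ceiling(a: str, b: str, n_shuffles: int = 20, z: float = 3.0) -> float:
    """Chance level of rotational identity for this sequence pair.

    Maximising identity over rotations, strands and gapped alignments
    gives unrelated monomers a substantial baseline identity (over 50%
    for short equal-length pairs), so a fixed low threshold cannot by
    itself establish homology. The ceiling is mean + z*sd of the
    rotational identity of ``a`` against shuffles of ``b`` (deterministic
    per pair).
    """
    import zlib

    seed = zlib.crc32((a + "|" + b).encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    chars = np.frombuffer(b.encode(), dtype=np.uint8)
    vals = []
    for _ in range(n_shuffles):
        shuffled = chars[rng.permutation(chars.size)].tobytes().decode()
        vals.append(rotational_identity(a, shuffled))
    return float(np.mean(vals) + z * np.std(vals))


# ---------------------------------------------------------------------------
# grouping


def _single_linkage(n: int, edges) -> list[list[int]]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def group(
    monomers: Sequence[MinedMonomer],
    variant_threshold: float = VARIANT_IDENTITY,
    family_threshold: float = FAMILY_IDENTITY,
    superfamily_threshold: float = SUPERFAMILY_IDENTITY,
    inclusive: bool = True,
) -> tuple[list[SatFamily], list[Superfamily]]:
    """Single-linkage grouping of monomers at the three identity levels.

    Identities are rounded to 0.1% before threshold comparison; by default
    a value exactly at the threshold joins the group (``inclusive``).
    Returns unranked families (consensus = most abundant variant) and the
    superfamilies with more than one member family.
    """

    # deduplicate by exact canonical sequence, pooling support
    merged: dict[str, MinedMonomer] = {}
    for m in monomers:
        key = m.consensus
        if key in merged:
            merged[key].support += m.support
        else:
            merged[key] = MinedMonomer(m.consensus, m.period, m.support, m.iteration, m.cluster_index)
    items = sorted(merged.values(), key=lambda m: (-m.support, m.consensus))
    n = len(items)
    if n == 0:
        return [], []

    ident = np.zeros((n, n))
    for i in range(n):
        ident[i, i] = 100.0
        for j in range(i + 1, n):
            if _upper_bound_identity(items[i].consensus, items[j].consensus) < superfamily_threshold - 5:
                val = 0.0
            else:
                val = round(rotational_identity(items[i].consensus, items[j].consensus), 1)
            ident[i, j] = ident[j, i] = val

    def edges(threshold):
        op = (lambda v: v >= threshold) if inclusive else (lambda v: v > threshold)
        return [(i, j) for i in range(n) for j in range(i + 1, n) if op(ident[i, j])]

    variant_groups = _single_linkage(n, edges(variant_threshold))
    # map each monomer to its variant representative (max support)
    variant_of = {}
    variant_reps = []
    for g in variant_groups:
        rep = max(g, key=lambda i: (items[i].support, items[i].consensus))
        variant_reps.append((rep, g))
        for i in g:
            variant_of[i] = len(variant_reps) - 1

    family_groups = _single_linkage(n, edges(family_threshold))
    families: list[SatFamily] = []
    family_of_monomer = {}
    for g in family_groups:
        vids = sorted({variant_of[i] for i in g})
        variants = []
        support = []
        for vid in vids:
            rep, members = variant_reps[vid]
            variants.append(items[rep].consensus)
            support.append(sum(items[i].support for i in members))
        order = sorted(range(len(variants)), key=lambda k: (-support[k], variants[k]))
        variants = [variants[k] for k in order]
        support = [support[k] for k in order]
        fam = SatFamily(consensus=variants[0], variants=variants, variant_support=support)
        for i in g:
            family_of_monomer[i] = len(families)
        families.append(fam)

    # the 50% superfamily level sits below the chance identity of short
    # unrelated monomers; require edges to clear the per-pair shuffle null
    def sf_edges():
        op = (lambda v, t: v >= t) if inclusive else (lambda v, t: v > t)
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                v = ident[i, j]
                if not op(v, superfamily_threshold) or v == 0.0:
                    continue
                if op(v, family_threshold) or v >= chance_identity_ceiling(
                    items[i].consensus, items[j].consensus
                ):
                    out.append((i, j))
        return out

    sf_groups = _single_linkage(n, sf_edges())
    superfamilies: list[Superfamily] = []
    for g in sf_groups:
        fams = sorted({family_of_monomer[i] for i in g})
        if len(fams) < 2:
            continue
        best = max(
            ident[i, j]
            for i in g
            for j in g
            if family_of_monomer[i] != family_of_monomer[j]
        )
        sf = Superfamily(id=len(superfamilies) + 1, member_indices=fams, defining_identity=float(best))
        for fi in fams:
            families[fi].superfamily_id = sf.id
        superfamilies.append(sf)

    return families, superfamilies


# ---------------------------------------------------------------------------
# naming


def is_telomeric(consensus: str) -> bool:
    """True when the canonical monomer is the vertebrate telomeric repeat
    TTAGGG or a perfect multimer of it."""
    n = len(consensus)
    if n % len(TELOMERE_MONOMER) != 0:
        return False
    k = n // len(TELOMERE_MONOMER)
    return canonical_rotation(consensus) == canonical_rotation(TELOMERE_MONOMER * k)


def name_families(
    families: Sequence[SatFamily],
    abundance_0b: Mapping[str, float],
    prefix: str,
) -> list[SatFamily]:
    """Assign catalogue ranks and names by decreasing 0B abundance.

    ``abundance_0b`` maps family consensus -> abundance (%); ties are
    broken by decreasing RUL, then lexicographic consensus. Names are
    ``<prefix>Sat<NN>-<RUL>`` with NN zero-padded to two digits and a
    ``-tel`` suffix for the telomeric repeat.
    """
    missing = [f.consensus for f in families if f.consensus not in abundance_0b]
    if missing:
        raise InvalidParameterError(f"abundance missing for {len(missing)} families")
    order = sorted(
        range(len(families)),
        key=lambda i: (
            -abundance_0b[families[i].consensus],
            -families[i].rul,
            families[i].consensus,
        ),
    )
    out = []
    for rank, i in enumerate(order, start=1):
        fam = families[i]
        fam.rank = rank
        suffix = "-tel" if is_telomeric(fam.consensus) else ""
        fam.name = f"{prefix}Sat{rank:02d}-{fam.rul}{suffix}"
        out.append(fam)
    return out


# ---------------------------------------------------------------------------
# output


def catalog_fasta_records(families: Sequence[SatFamily]) -> list[tuple[str, str]]:
    records = []
    for fam in families:
        base = fam.name or f"family{fam.rank or 0}"
        for k, variant in enumerate(fam.variants, start=1):
            records.append((f"{base}#variant{k}", variant))
    return records


def catalog_table(families: Sequence[SatFamily]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "name": fam.name,
                "rank": fam.rank,
                "rul": fam.rul,
                "at_percent": round(fam.at_percent, 1),
                "v": fam.v,
                "superfamily": fam.superfamily_id,
                "support": fam.support,
            }
            for fam in sorted(families, key=lambda f: f.rank or 0)
        ]
    )
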