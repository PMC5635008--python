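"""Synthetic 0B/1B genome pairs with planted satellite DNA and read simulation.

The generator emulates the study design behind satellitome mining from a
B-chromosome system: two individuals of one species, one lacking (0B) and
one carrying (1B) a supernumerary B chromosome. Genomes are represented as
haploid strings; the 1B string equals the 0B string plus a B segment whose
length is a fraction ``f`` (default 0.08) of the 0B haploid complement.
Satellite families are planted as head-to-tail tandem arrays carved into a
random background, each copy independently mutated at the family's
intra-family divergence; ground truth (exact coordinates, copy numbers,
genomic fractions) is recorded for parameter-recovery tests.

Read simulation mirrors 2 x 101 bp paired-end sequencing with a pure
substitution error model. Because real genomes are diploid, adding one B to
a diploid A complement dilutes an A-only satellite by f/2, not f; the
default ``diploid_equivalent`` mode therefore duplicates the A portion
(not the B) before sampling fragments, so the dilution factor is
1/(1 + f/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import BASES, decode, decode_rows, encode, revcomp_codes
from .errors import CapacityError, InvalidParameterError, SamplingError

READ_LENGTH_DEFAULT = 101
PHRED_PLACEHOLDER = "F"  # Q37


# ---------------------------------------------------------------------------
# specifications and ground truth


@dataclass
class FamilySpec:
    """Parameters of one planted satellite DNA family.

    rul
        Repeat unit length in bp (monomer length); 6..1000.
    at_frac
        Expected A+T fraction of the ancestral monomer.
    copies_0b / copies_b
        Tandem copy numbers planted in the A complement and in the B
        segment respectively.
    intra_divergence
        Expected per-site substitution fraction of each planted copy
        relative to its variant consensus (0..0.3).
    n_variants
        Number of sequence variants (divergent forms at roughly 85-95%
        identity to the ancestor) the family is split into.
    superfamily_partner / partner_identity
        Optional label of a previously listed family; this family's
        monomer is then derived from the partner's at the target identity
        (0.50..0.80), so the two group as distinct families of one
        superfamily.
    b_restricted
        Tandem arrays occur only in the B segment (copies_0b must be 0).
    dispersed_copies_0b
        Single, non-tandem monomer copies scattered in the A complement;
        used to emulate B-specific satellites that are detectable in 0B
        reads at tiny abundance without tandem structure.
    """

    label: str
    rul: int
    copies_0b: int = 0
    copies_b: int = 0
    at_frac: float = 0.55
    intra_divergence: float = 0.02
    n_variants: int = 1
    superfamily_partner: Optional[str] = None
    partner_identity: float = 0.65
    b_restricted: bool = False
    dispersed_copies_0b: int = 0

    def __post_init__(self) -> None:
        if not 6 <= self.rul <= 1000:
            raise InvalidParameterError(f"{self.label}: rul={self.rul} outside 6..1000")
        if not 0.0 <= self.at_frac <= 1.0:
            raise InvalidParameterError(f"{self.label}: at_frac outside [0,1]")
        if not 0.0 <= self.intra_divergence <= 0.3:
            raise InvalidParameterError(f"{self.label}: intra_divergence outside [0,0.3]")
        if self.n_variants < 1:
            raise InvalidParameterError(f"{self.label}: n_variants must be >= 1")
        if min(self.copies_0b, self.copies_b, self.dispersed_copies_0b) < 0:
            raise InvalidParameterError(f"{self.label}: negative copy number")
        if self.b_restricted and (self.copies_0b != 0 or self.copies_b <= 0):
            raise InvalidParameterError(
                f"{self.label}: b_restricted requires copies_0b=0 and copies_b>0"
            )
        if self.superfamily_partner is not None and not 0.5 <= self.partner_identity < 0.8:
            raise InvalidParameterError(
                f"{self.label}: partner identity target must lie in [0.5, 0.8)"
            )


@dataclass
class TruthRow:
    label: str
    monomer: str
    rul: int
    copies_0b: int
    copies_b: int
    dispersed_0b: int
    fraction_0b: float
    fraction_1b: float
    b_restricted: bool
    variants: list[str] = field(default_factory=list)
    # (genome, start, end, variant_index); genome is "A" or "B"
    intervals: list[tuple[str, int, int, int]] = field(default_factory=list)


@dataclass
class TruthTable:
    rows: list[TruthRow]
    seed: int
    b_fraction: float
    len_0b: int = 0
    len_1b: int = 0

    def __iter__(self):
        return iter(self.rows)

    def __getitem__(self, label: str) -> TruthRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def expected_read_fraction(self, label: str, genome: str, diploid_equivalent: bool = True) -> float:
        """Expected fraction of read nucleotides drawn from the family.

        For the 1B genome in diploid-equivalent mode the A portion is
        weighted twice, so an A-only family is diluted by 1/(1 + f/2).
        """
        row = self[label]
        nt_a = (row.copies_0b + row.dispersed_0b) * row.rul
        nt_b = row.copies_b * row.rul
        len_b = self.len_1b - self.len_0b
        if genome == "0B":
            return nt_a / self.len_0b
        if genome != "1B":
            raise InvalidParameterError(f"unknown genome label {genome!r}")
        if diploid_equivalent:
            return (2 * nt_a + nt_b) / (2 * self.len_0b + len_b)
        return (nt_a + nt_b) / self.len_1b

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "label": r.label,
                    "rul": r.rul,
                    "copies_0b": r.copies_0b,
                    "copies_b": r.copies_b,
                    "dispersed_0b": r.dispersed_0b,
                    "fraction_0b": r.fraction_0b,
                    "fraction_1b": r.fraction_1b,
                    "b_restricted": r.b_restricted,
                    "monomer": r.monomer,
                    "seed": self.seed,
                }
                for r in self.rows
            ]
        ).to_csv(path, sep="\t", index=False)


@dataclass
class GenomePair:
    seq_0b: str
    seq_1b: str
    b_fraction: float
    truth: TruthTable

    def __post_init__(self) -> None:
        assert self.seq_1b.startswith(self.seq_0b)

    @property
    def b_segment(self) -> str:
        return self.seq_1b[len(self.seq_0b) :]

    def simulation_template(self, genome: str, diploid_equivalent: bool = True) -> str:
        """Sequence from which reads of the given genome are sampled."""
        if genome == "0B":
            return self.seq_0b + self.seq_0b if diploid_equivalent else self.seq_0b
        if genome == "1B":
            return self.seq_0b + self.seq_1b if diploid_equivalent else self.seq_1b
        raise InvalidParameterError(f"unknown genome label {genome!r}")


# ---------------------------------------------------------------------------
# monomer and genome construction


def build_monomer(rul: int, at_frac: float, seed: int) -> str:
    """Random monomer of length ``rul`` with expected A+T fraction ``at_frac``."""
    if rul < 1:
        raise InvalidParameterError(f"rul must be >= 1, got {rul}")
    if not 0.0 <= at_frac <= 1.0:
        raise InvalidParameterError(f"at_frac must lie in [0,1], got {at_frac}")
    rng = np.random.default_rng(seed)
    is_at = rng.random(rul) < at_frac
    pick = rng.integers(0, 2, size=rul)
    # A/T for AT positions, C/G otherwise
    codes = np.where(is_at, np.where(pick == 0, 0, 3), np.where(pick == 0, 1, 2))
    return decode(codes.astype(np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply substitutions at an expected ``rate`` per site.

    ``rate`` is an evolutionary distance: each site receives a Poisson
    number of substitution events (uniform among the three alternative
    bases), so back- and multiple hits occur and a Kimura-type estimator
    recovers ``rate`` asymptotically. The realised mismatch fraction to
    the input is (3/4)(1 - exp(-4 rate/3)).
    """
    codes = encode(seq).copy()
    hits = rng.poisson(rate, size=codes.size)
    for k in range(1, int(hits.max(initial=0)) + 1):
        mask = hits >= k
        codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return decode(codes.astype(np.uint8))


def derive_at_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Derive a sequence at approximately the target identity to ``seq``.

    Substitutes a fixed fraction 1-identity of sites (always to a
    different base), so pairwise identity is 1-identity exactly up to the
    alignment convention.
    """
    n = len(seq)
    n_sub = int(round((1.0 - identity) * n))
    pos = rng.choice(n, size=n_sub, replace=False)
    codes = encode(seq).copy()
    codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_sub)) % 4
    return decode(codes.astype(np.uint8))


def _random_background(length: int, rng: np.random.Generator, at_frac: Optional[float]) -> np.ndarray:
    if at_frac is None:
        return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)
    is_at = rng.random(length) < at_frac
    pick = rng.integers(0, 2, size=length)
    return np.where(is_at, np.where(pick == 0, 0, 3), np.where(pick == 0, 1, 2)).astype(np.uint8)


def _variant_copy_split(copies: int, n_variants: int) -> list[int]:
    """Split a copy count over variants with strictly decreasing weights."""
    weights = np.array([2.0 ** -k for k in range(n_variants)])
    weights /= weights.sum()
    counts = np.floor(weights * copies).astype(int)
    counts[0] += copies - counts.sum()
    return counts.tolist()


def _carve(
    background: np.ndarray,
    pieces: list[tuple[np.ndarray, str, int, str]],
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[str, int, int, int]]]:
    """Overwrite non-overlapping random intervals of background with pieces.

    Each piece is (codes, family_label, variant_index, genome_tag). The
    background length is preserved. Returns the edited sequence and the
    recorded intervals (family, start, end, variant).
    """
    total = sum(len(p[0]) for p in pieces)
    free = len(background) - total
    if free < 0:
        raise CapacityError("planted arrays exceed background capacity")
    order = rng.permutation(len(pieces))
    gaps = np.sort(rng.integers(0, free + 1, size=len(pieces)))
    out = background.copy()
    intervals = []
    offset = 0
    for rank, idx in enumerate(order):
        codes, label, variant, tag = pieces[idx]
        start = int(gaps[rank]) + offset
        out[start : start + len(codes)] = codes
        intervals.append((label, tag, start, start + len(codes), variant))
        offset += len(codes)
    return out, [(tag, s, e, v, label) for (label, tag, s, e, v) in intervals]


def plant_families(
    specs: Sequence[FamilySpec],
    background_length: int,
    f: float,
    seed: int,
    background_at: Optional[float] = None,
    variant_divergence: float = 0.08,
) -> GenomePair:
    """Build a 0B/1B genome pair with the given satellite families planted.

    Tandem arrays (one array per variant) are carved into a random
    background at non-overlapping positions, so the 0B genome length is
    exactly ``background_length`` and the B segment length is exactly
    round(f * background_length). Raises CapacityError naming the family
    whose arrays do not fit.
    """
    labels = [s.label for s in specs]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("family labels must be unique")
    if not 0.0 <= f < 1.0:
        raise InvalidParameterError(f"b fraction f={f} outside [0,1)")
    ss = np.random.SeedSequence(seed)
    rng_bg, rng_place, rng_fam = [np.random.default_rng(s) for s in ss.spawn(3)]

    len_b = int(round(f * background_length))
    background_a = _random_background(background_length, rng_bg, background_at)
    background_b = _random_background(len_b, rng_bg, background_at)

    monomers: dict[str, str] = {}
    pieces_a: list[tuple[np.ndarray, str, int, str]] = []
    pieces_b: list[tuple[np.ndarray, str, int, str]] = []
    rows: list[TruthRow] = []

    cap_a = background_length
    cap_b = len_b
    used_a = used_b = 0

    for spec in specs:
        frng = np.random.default_rng(rng_fam.integers(0, 2**31 - 1))
        if spec.superfamily_partner is not None:
            if spec.superfamily_partner not in monomers:
                raise InvalidParameterError(
                    f"{spec.label}: superfamily partner {spec.superfamily_partner!r} "
                    "must be listed earlier"
                )
            base = monomers[spec.superfamily_partner]
            if len(base) != spec.rul:
                base = build_monomer(spec.rul, spec.at_frac, int(frng.integers(2**31 - 1)))
                monomer = base
            else:
                monomer = derive_at_identity(base, spec.partner_identity, frng)
        else:
            monomer = build_monomer(spec.rul, spec.at_frac, int(frng.integers(2**31 - 1)))
        monomers[spec.label] = monomer

        variants = [monomer]
        for _ in range(spec.n_variants - 1):
            variants.append(mutate(monomer, variant_divergence, frng))

        def tandem_array(variant_seq: str, copies: int) -> np.ndarray:
            parts = [encode(mutate(variant_seq, spec.intra_divergence, frng)) for _ in range(copies)]
            return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)

        row = TruthRow(
            label=spec.label,
            monomer=monomer,
            rul=spec.rul,
            copies_0b=spec.copies_0b,
            copies_b=spec.copies_b,
            dispersed_0b=spec.dispersed_copies_0b,
            fraction_0b=0.0,
            fraction_1b=0.0,
            b_restricted=spec.b_restricted,
            variants=list(variants),
        )

        if spec.copies_0b:
            for v, c in enumerate(_variant_copy_split(spec.copies_0b, spec.n_variants)):
                if c:
                    pieces_a.append((tandem_array(variants[v], c), spec.label, v, "A"))
        for _ in range(spec.dispersed_copies_0b):
            pieces_a.append((encode(mutate(monomer, spec.intra_divergence, frng)), spec.label, 0, "A"))
        if spec.copies_b:
            for v, c in enumerate(_variant_copy_split(spec.copies_b, spec.n_variants)):
                if c:
                    pieces_b.append((tandem_array(variants[v], c), spec.label, v, "B"))

        used_a += (spec.copies_0b + spec.dispersed_copies_0b) * spec.rul
        used_b += spec.copies_b * spec.rul
        if used_a >= cap_a or used_b > cap_b:
            raise CapacityError(
                f"arrays of family {spec.label!r} do not fit "
                f"(A: {used_a}/{cap_a} nt, B: {used_b}/{cap_b} nt)"
            )
        rows.append(row)

    seq_a, intervals_a = _carve(background_a, pieces_a, rng_place)
    seq_b, intervals_b = _carve(background_b, pieces_b, rng_place) if pieces_b else (background_b, [])

    len_0b = background_length
    len_1b = background_length + len_b
    for row in rows:
        nt_a = (row.copies_0b + row.dispersed_0b) * row.rul
        nt_b = row.copies_b * row.rul
        row.fraction_0b = nt_a / len_0b
        row.fraction_1b = (nt_a + nt_b) / len_1b
        row.intervals = [
            (tag, s, e, v)
            for (tag, s, e, v, label) in intervals_a + intervals_b
            if label == row.label
        ]

    truth = TruthTable(rows=rows, seed=seed, b_fraction=f, len_0b=len_0b, len_1b=len_1b)
    seq_0b = decode(seq_a)
    seq_1b = seq_0b + decode(seq_b)
    return GenomePair(seq_0b=seq_0b, seq_1b=seq_1b, b_fraction=f, truth=truth)


def example_satellitome(background_length: int = 1_200_000) -> list[FamilySpec]:
    """A ten-family benchmark satellitome spanning RUL 18-365 bp and
    abundances 0.01-5% of the A complement.

    Long monomers sit at the abundant end (their clusters form while the
    sample coverage is still low and assembly is clean); the two rarest
    families are at the detection floor of desk-scale libraries and are
    expected to be missed at moderate depth.
    """
    grid = [
        ("f01", 51, 5.0),
        ("f02", 236, 2.0),
        ("f03", 365, 1.0),
        ("f04", 178, 0.5),
        ("f05", 91, 0.25),
        ("f06", 58, 0.12),
        ("f07", 33, 0.06),
        ("f08", 21, 0.03),
        ("f09", 27, 0.015),
        ("f10", 18, 0.01),
    ]
    specs = []
    for label, rul, pct in grid:
        copies = max(2, int(round(pct / 100 * background_length / rul)))
        specs.append(
            FamilySpec(
                label=label,
                rul=rul,
                copies_0b=copies,
                copies_b=max(1, copies // 25),
                intra_divergence=0.02,
                at_frac=0.55,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadLibrary:
    """Paired reads held as uint8 code matrices (one row per read)."""

    r1: np.ndarray
    r2: np.ndarray
    read_len: int
    error_rate: float
    seed: int
    label: str = "lib"

    def __len__(self) -> int:
        return self.r1.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    @property
    def total_nt(self) -> int:
        return 2 * self.n_pairs * self.read_len

    def reads(self) -> np.ndarray:
        """All mates as one (2*n_pairs, read_len) matrix: r1 block then r2."""
        return np.concatenate([self.r1, self.r2], axis=0)

    def sequences(self) -> list[str]:
        return decode_rows(self.reads())

    def subset(self, index: np.ndarray) -> "ReadLibrary":
        return ReadLibrary(
            r1=self.r1[index],
            r2=self.r2[index],
            read_len=self.read_len,
            error_rate=self.error_rate,
            seed=self.seed,
            label=self.label,
        )

    def drop_pairs(self, mask: np.ndarray) -> "ReadLibrary":
        return self.subset(~np.asarray(mask, dtype=bool))

    def to_fastq(self, path1, path2) -> None:
        qual = PHRED_PLACEHOLDER * self.read_len
        for path, mat, mate in ((path1, self.r1, 1), (path2, self.r2, 2)):
            seqs = decode_rows(mat)
            with open(path, "w") as fh:
                for i, s in enumerate(seqs):
                    fh.write(f"@{self.label}_{i}/{mate}\n{s}\n+\n{qual}\n")


def simulate_reads(
    genome: str,
    n_pairs: int,
    read_len: int = READ_LENGTH_DEFAULT,
    insert_mean: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
    label: str = "lib",
) -> ReadLibrary:
    """Simulate paired-end reads with uniform fragment starts.

    Fragments of fixed length ``insert_mean`` start uniformly on the
    genome; each pair is assigned a random strand; per-base substitution
    errors are applied at ``error_rate``. Deterministic given ``seed``.
    """
    if n_pairs <= 0:
        raise InvalidParameterError(f"n_pairs must be positive, got {n_pairs}")
    if not read_len <= insert_mean <= len(genome):
        raise InvalidParameterError(
            f"need read_len <= insert_mean <= genome length "
            f"({read_len} <= {insert_mean} <= {len(genome)})"
        )
    if not 0.0 <= error_rate < 1.0:
        raise InvalidParameterError(f"error_rate outside [0,1): {error_rate}")
    rng = np.random.default_rng(seed)
    gcodes = encode(genome)
    starts = rng.integers(0, len(genome) - insert_mean + 1, size=n_pairs)
    idx = starts[:, None] + np.arange(read_len)[None, :]
    fwd1 = gcodes[idx]
    idx2 = (starts + insert_mean - read_len)[:, None] + np.arange(read_len)[None, :]
    fwd2 = revcomp_codes(gcodes[idx2])
    minus = rng.random(n_pairs) < 0.5
    r1 = np.where(minus[:, None], fwd2, fwd1)
    r2 = np.where(minus[:, None], fwd1, fwd2)
    if error_rate > 0:
        for mat in (r1, r2):
            hit = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
            mat[hit] = (mat[hit] + shift) % 4
    return ReadLibrary(
        r1=r1.astype(np.uint8),
        r2=r2.astype(np.uint8),
        read_len=read_len,
        error_rate=error_rate,
        seed=seed,
        label=label,
    )


def read_fastq_pair(path1, path2, label: str = "lib") -> ReadLibrary:
    """Load a paired FASTQ library into code matrices."""
    from Bio import SeqIO

    def load(path):
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
        if not seqs:
            raise SamplingError(f"no reads in {path}")
        length = len(seqs[0])
        return np.vstack([encode(s) for s in seqs]), length

    m1, l1 = load(path1)
    m2, l2 = load(path2)
    if m1.shape != m2.shape:
        raise SamplingError("mate files differ in read count or length")
    return ReadLibrary(r1=m1, r2=m2, read_len=l1, error_rate=float("nan"), seed=-1, label=label)


def write_fasta(path, records: Sequence[tuple[str, str]], width: int = 60) -> None:
    """Write (name, sequence) records as 60-column wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
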