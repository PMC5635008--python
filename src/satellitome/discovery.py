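"""Iterative satellite DNA mining from short-read libraries.

The protocol mirrors iterative repeat-discovery pipelines built on graph
clustering of a low-coverage read sample: sample reads, join reads that
share canonical k-mers into connected components, test each component for
tandem periodicity, call a consensus monomer, subtract reads homologous to
everything found so far, double the sample size and repeat until an
iteration yields nothing new. Because a satellite's copy number multiplies
its effective coverage, each doubling exposes the next, rarer tier of
families while the unique background stays too thin to assemble.

Two period-detection paths are used. For periods short enough that a
single read spans two full copies, every read votes for its own best
period by self-comparison at each candidate offset. For longer monomers
(up to several times the read length) the cluster is first greedily
assembled into a quasi-periodic contig by overlap extension — reads from
different copies of the array overlap in monomer coordinate space — and
the period is estimated by self-alignment offset scoring on the contig.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import decode, decode_rows, kmer_codes
from .catalog import MinedMonomer, rotational_identity, FAMILY_IDENTITY
from .errors import InvalidParameterError, SamplingError
from .quantify import Masker
from .simgen import ReadLibrary

CLUSTER_K = 17
MIN_SHARED_KMERS = 5
MIN_CLUSTER_SIZE = 10
BRIDGE_BUCKET = 50

MIN_PERIOD = 5
MAX_PERIOD = 400
TANDEM_SCORE = 0.80

SUBTRACT_MIN_IDENTITY = 0.80
SUBTRACT_MIN_COV = 0.50

START_PAIRS = 200_000


# ---------------------------------------------------------------------------
# sampling


def sample_reads(library: ReadLibrary, n_pairs: int, seed: int) -> ReadLibrary:
    """Uniform sample of read pairs without replacement (order-stable)."""
    if n_pairs > library.n_pairs:
        raise SamplingError(f"requested {n_pairs} pairs from a library of {library.n_pairs}")
    if n_pairs == library.n_pairs:
        return library
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(library.n_pairs, size=n_pairs, replace=False))
    return library.subset(idx)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ReadCluster:
    """A connected component of the k-mer sharing graph."""

    member_ids: np.ndarray  # row indices into the clustered read matrix
    reads: np.ndarray  # (n_members, read_len) codes
    n_edges: Optional[int] = None

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def density(self) -> Optional[float]:
        if self.n_edges is None or self.size < 2:
            return None
        return 2 * self.n_edges / (self.size * (self.size - 1))

    def sequences(self) -> list[str]:
        return decode_rows(self.reads)


class _DSU:
    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_reads(
    reads: np.ndarray,
    k: int = CLUSTER_K,
    min_shared_kmers: int = MIN_SHARED_KMERS,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    bridge_bucket: int = BRIDGE_BUCKET,
) -> list[ReadCluster]:
    """Connected components of the canonical k-mer sharing graph.

    Reads are nodes; an edge joins two reads sharing at least
    ``min_shared_kmers`` canonical k-mers. K-mers carried by more than
    ``bridge_bucket`` reads are treated as unambiguous repeat words and
    union their whole bucket directly (such reads share many k-mers
    anyway); small buckets accumulate exact pair counts. Components of at
    least ``min_cluster_size`` reads are returned, largest first.
    """
    if not 11 <= k <= 31:
        raise InvalidParameterError(f"k={k} outside [11, 31]")
    reads = np.atleast_2d(reads)
    n = reads.shape[0]
    if n == 0:
        return []
    codes = kmer_codes(reads, k)
    # unique k-mers per read
    kmer_list = []
    read_list = []
    for i in range(n):
        u = np.unique(codes[i])
        kmer_list.append(u)
        read_list.append(np.full(u.size, i, dtype=np.int64))
    kmers = np.concatenate(kmer_list)
    rids = np.concatenate(read_list)
    order = np.argsort(kmers, kind="stable")
    kmers = kmers[order]
    rids = rids[order]
    boundaries = np.flatnonzero(np.diff(kmers)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [kmers.size]])

    dsu = _DSU(n)
    edge_pairs: set[tuple[int, int]] = set()
    pair_chunks: list[np.ndarray] = []
    _tri_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    sizes = ends - starts
    for s, e in zip(starts[sizes >= 2], ends[sizes >= 2]):
        bucket = np.sort(rids[s:e])
        if bucket.size > bridge_bucket:
            # a k-mer carried by this many sampled reads is a repeat word;
            # such reads share many k-mers, so union the bucket directly
            first = int(bucket[0])
            for r in bucket[1:]:
                dsu.union(first, int(r))
                edge_pairs.add((first, int(r)))
            continue
        tri = _tri_cache.get(bucket.size)
        if tri is None:
            tri = _tri_cache[bucket.size] = np.triu_indices(bucket.size, k=1)
        ai, bi = tri
        pair_chunks.append(bucket[ai].astype(np.int64) * n + bucket[bi])
    if pair_chunks:
        pairs = np.concatenate(pair_chunks)
        keys, counts = np.unique(pairs, return_counts=True)
        for key in keys[counts >= min_shared_kmers]:
            a, b = divmod(int(key), n)
            dsu.union(a, b)
            edge_pairs.add((a, b))

    roots = np.array([dsu.find(i) for i in range(n)])
    comp: dict[int, list[int]] = {}
    for i, r in enumerate(roots):
        comp.setdefault(int(r), []).append(i)
    clusters = []
    for members in comp.values():
        if len(members) < min_cluster_size:
            continue
        ids = np.array(sorted(members), dtype=np.int64)
        idset = set(members)
        n_edges = sum(1 for (a, b) in edge_pairs if a in idset and b in idset)
        clusters.append(ReadCluster(member_ids=ids, reads=reads[ids], n_edges=n_edges))
    clusters.sort(key=lambda c: (-c.size, int(c.member_ids[0])))
    return clusters


# ---------------------------------------------------------------------------
# tandem detection


def _per_read_period_scores(reads: np.ndarray, min_period: int, max_period: int) -> tuple[np.ndarray, np.ndarray]:
    """Self-identity of each read at each candidate offset.

    Returns (periods, score matrix of shape n_periods x n_reads). Only
    periods with two full copies per read (p <= (L-1)//2) are scored.
    """
    length = reads.shape[1]
    pmax = min(max_period, (length - 1) // 2)
    periods = np.arange(min_period, pmax + 1)
    scores = np.zeros((periods.size, reads.shape[0]))
    for i, p in enumerate(periods):
        scores[i] = (reads[:, p:] == reads[:, :-p]).mean(axis=1)
    return periods, scores


def _smallest_good_period(periods: np.ndarray, score: np.ndarray, threshold: float, slack: float = 0.03) -> Optional[int]:
    """Smallest period whose score clears both the threshold and the best
    score minus ``slack`` (guards against selecting multiples)."""
    if score.size == 0:
        return None
    best = float(score.max())
    if best < threshold:
        return None
    ok = np.flatnonzero((score >= threshold) & (score >= best - slack))
    return int(periods[ok[0]]) if ok.size else None


def _phase_consensus(reads: np.ndarray, period: int, reference: np.ndarray, min_identity: float = 0.7) -> str:
    """Majority consensus over reads phase-aligned to a reference monomer.

    Each read is slid against the tiled reference over all phases; the
    best phase maps read position i to monomer column (i+s) mod p. Ties in
    the per-column vote break alphabetically (A<C<G<T).
    """
    length = reads.shape[1]
    tiled = np.tile(reference, length // period + 2)
    counts = np.zeros((4, period), dtype=np.int64)
    cols = np.arange(length)
    for read in reads:
        best_s, best_hits = 0, -1
        for s in range(period):
            hits = int((read == tiled[s : s + length]).sum())
            if hits > best_hits:
                best_hits, best_s = hits, s
        if best_hits / length < min_identity:
            continue
        np.add.at(counts, (read.astype(np.int64), (cols + best_s) % period), 1)
    if counts.sum() == 0:
        return decode(reference.astype(np.uint8))
    return decode(np.argmax(counts, axis=0).astype(np.uint8))


def _core_reads(reads: np.ndarray, k: int = 12, core_fraction: float = 0.8) -> np.ndarray:
    """Indices of reads lying entirely inside the repeat.

    A read fully inside a tandem array carries only high-multiplicity
    k-mers (every copy of the array repeats them); reads straddling an
    array boundary, or background reads swept into the cluster, carry a
    stretch of rare k-mers. Keeping only reads whose k-mers are mostly
    repeated prevents greedy assembly from walking out of the array.
    """
    codes = kmer_codes(reads, k)
    uniq, counts = np.unique(codes, return_counts=True)
    thr = max(4, reads.shape[0] // 50)
    frequent = uniq[counts >= thr]
    hit = np.isin(codes, frequent)
    frac = hit.mean(axis=1)
    # adaptive cut: intra-family divergence lowers every read's repeated
    # k-mer fraction, so scale the cut to the well-covered reads
    cut = min(core_fraction, core_fraction * float(np.percentile(frac, 90)))
    core = np.flatnonzero(frac >= max(cut, 0.05))
    return core if core.size else np.arange(reads.shape[0])


def _greedy_assemble(
    reads: np.ndarray,
    target_len: int,
    min_overlap: int = 30,
    max_mismatch: float = 0.15,
    max_steps: int = 400,
    seed_read: Optional[int] = None,
    exclude: Optional[set] = None,
) -> tuple[np.ndarray, set]:
    """Greedy right-extension assembly of cluster reads.

    Reads from different copies of a tandem array overlap in monomer
    coordinates, so the contig follows the periodic consensus path and
    wraps around the monomer; its self-alignment offsets reveal the
    period. Deterministic: candidates are scanned in a fixed order and
    the longest acceptable extension wins. Returns (contig, used reads).
    """
    length = reads.shape[1]
    k = 12
    codes = kmer_codes(reads, k)
    index: dict[int, list[int]] = {}
    for i in range(reads.shape[0]):
        for c in np.unique(codes[i]):
            index.setdefault(int(c), []).append(i)

    from collections import Counter

    if seed_read is None:
        # seed: read sharing the most k-mers with the rest of the cluster
        cnt: Counter = Counter()
        for c, members in index.items():
            if len(members) > 1:
                for m in members:
                    cnt[m] += len(members) - 1
        pool = [i for i in range(reads.shape[0]) if not exclude or i not in exclude]
        if not pool:
            pool = list(range(reads.shape[0]))
        seed_read = max(pool, key=lambda i: (cnt.get(i, 0), -i))
    contig = list(reads[seed_read])
    used = {seed_read}

    for _ in range(max_steps):
        if len(contig) >= target_len:
            break
        tail = np.array(contig[-length:], dtype=np.uint8)
        tail_kmers = set(int(x) for x in np.unique(kmer_codes(tail[None, :], k)))
        cand: Counter = Counter()
        for c in tail_kmers:
            for m in index.get(c, ()):
                if m not in used:
                    cand[m] += 1
        best = None  # (extension, read idx, overlap)
        for m, shared in cand.items():
            if shared < 3:
                continue
            read = reads[m]
            # best (largest) overlap of read prefix with tail suffix
            for o in range(min(length, len(tail)) - 1, min_overlap - 1, -1):
                mism = int((tail[-o:] != read[:o]).sum())
                if mism <= max_mismatch * o:
                    ext = length - o
                    if ext > 0 and (best is None or ext > best[0] or (ext == best[0] and m < best[1])):
                        best = (ext, m, o)
                    break
        if best is None:
            break
        ext, m, o = best
        contig.extend(reads[m][o:])
        used.add(m)
    return np.array(contig, dtype=np.uint8), used


def _contig_period(contig: np.ndarray, min_period: int, max_period: int, threshold: float) -> Optional[int]:
    length = contig.size
    pmax = min(max_period, length // 2)
    if pmax < min_period:
        return None
    periods = np.arange(min_period, pmax + 1)
    scores = np.array([(contig[p:] == contig[:-p]).mean() for p in periods])
    return _smallest_good_period(periods, scores, threshold, slack=0.02)


def _fold_contig(contig: np.ndarray, period: int) -> str:
    counts = np.zeros((4, period), dtype=np.int64)
    cols = np.arange(contig.size) % period
    np.add.at(counts, (contig.astype(np.int64), cols), 1)
    return decode(np.argmax(counts, axis=0).astype(np.uint8))


def detect_tandem(
    cluster: ReadCluster,
    min_period: int = MIN_PERIOD,
    max_period: int = MAX_PERIOD,
    score_threshold: float = TANDEM_SCORE,
    min_support: int = 5,
    max_reads: int = 400,
) -> Optional[MinedMonomer]:
    """Estimate the repeat period of a cluster and call a consensus monomer.

    Returns None when no periodicity clears the score threshold (unique
    sequence clusters are a valid, common outcome).
    """
    reads = cluster.reads
    if reads.shape[0] > 10 * max_reads:
        sel = np.linspace(0, reads.shape[0] - 1, 10 * max_reads).astype(int)
        reads = reads[sel]
    # restrict to reads whose k-mers recur within the cluster: in large
    # mixed components this concentrates on the tandem repeat and drops
    # the unique background swept in by array-boundary reads
    if reads.shape[0] > 2 * min_support:
        reads = reads[_core_reads(reads)]
    if reads.shape[0] > max_reads:
        sel = np.linspace(0, reads.shape[0] - 1, max_reads).astype(int)
        reads = reads[sel]
    length = reads.shape[1]

    periods, scores = _per_read_period_scores(reads, min_period, max_period)
    votes: dict[int, list[int]] = {}
    for ri in range(reads.shape[0]):
        p = _smallest_good_period(periods, scores[:, ri], score_threshold)
        if p is not None:
            votes.setdefault(p, []).append(ri)
    # pool votes for near-identical periods is unnecessary: substitution-only
    # divergence keeps the period exact
    if votes:
        period, voters = max(votes.items(), key=lambda kv: (len(kv[1]), -kv[0]))
        if len(voters) >= min_support:
            pi = int(np.flatnonzero(periods == period)[0])
            ref_read = reads[voters[int(np.argmax(scores[pi, voters]))]]
            consensus = _phase_consensus(reads[voters], period, ref_read[:period])
            return MinedMonomer(
                consensus=consensus,
                period=period,
                support=len(voters),
                cluster_index=int(cluster.member_ids[0]),
            )

    # long-period path: assemble, then score self-alignment offsets.
    # Cheap precheck: a tandem cluster carries k-mers present in a large
    # fraction of its reads, unlike overlap chains of unique background.
    if reads.shape[0] >= min_support:
        _, kcounts = np.unique(kmer_codes(reads, 12), return_counts=True)
        if int(kcounts.max(initial=0)) < max(min_support, int(0.2 * reads.shape[0])):
            return None
        core_reads = reads
        exclude: set = set()
        for _attempt in range(3):
            contig, used = _greedy_assemble(
                core_reads, target_len=3 * max_period + 2 * length, exclude=exclude
            )
            if contig.size >= 2 * length:
                period = _contig_period(
                    contig, max(min_period, (length - 1) // 2), max_period, score_threshold
                )
                if period is not None and contig.size >= 2 * period:
                    consensus = _fold_contig(contig, period)
                    support = min(core_reads.shape[0], contig.size // length + 1)
                    return MinedMonomer(
                        consensus=consensus,
                        period=period,
                        support=int(support),
                        cluster_index=int(cluster.member_ids[0]),
                    )
            exclude |= used
            if len(exclude) >= core_reads.shape[0]:
                break
    return None


# ---------------------------------------------------------------------------
# subtraction and the mining loop


def subtract_reads(
    library: ReadLibrary,
    catalog: Sequence[MinedMonomer],
    min_identity: float = SUBTRACT_MIN_IDENTITY,
    min_cov: float = SUBTRACT_MIN_COV,
) -> tuple[ReadLibrary, int]:
    """Remove read pairs homologous to any catalogued monomer.

    A pair is removed when either mate aligns to a monomer (circular,
    both strands) at >= ``min_identity`` over >= ``min_cov`` of the read.
    """
    if not catalog:
        return library, 0
    masker = Masker(
        [(f"m{i}", m.consensus) for i, m in enumerate(catalog)],
        min_identity=min_identity,
        min_len=int(min_cov * library.read_len),
    )
    hit1 = masker.matches(library.r1)
    hit2 = masker.matches(library.r2)
    drop = hit1 | hit2
    return library.drop_pairs(drop), int(drop.sum())


@dataclass
class IterationLog:
    iteration: int
    sample_pairs: int
    clusters: int
    new_monomers: int
    pairs_subtracted: int
    pairs_remaining: int


@dataclass
class MiningResult:
    monomers: list[MinedMonomer]
    log: list[IterationLog] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(row) for row in self.log])


@dataclass
class MineConfig:
    start_pairs: int = START_PAIRS
    max_iterations: int = 12
    k: int = CLUSTER_K
    min_shared_kmers: int = MIN_SHARED_KMERS
    min_cluster_size: int = MIN_CLUSTER_SIZE
    min_period: int = MIN_PERIOD
    max_period: int = MAX_PERIOD
    score_threshold: float = TANDEM_SCORE
    min_support: int = 5
    max_clusters_per_iteration: int = 500
    subtract_min_identity: float = SUBTRACT_MIN_IDENTITY
    subtract_min_cov: float = SUBTRACT_MIN_COV
    dedup_identity: float = FAMILY_IDENTITY
    stop_after_empty: int = 2
    seed: int = 0


def mine_satellitome(library: ReadLibrary, config: MineConfig = MineConfig()) -> MiningResult:
    """Run the iterative sample/cluster/detect/subtract protocol.

    The sample doubles each iteration; mining stops once
    ``stop_after_empty`` consecutive iterations yield no monomer that
    fails to group (at the family identity level) with something already
    found, or when the library is exhausted. A patience of more than one
    iteration lets the doubling bridge abundance gaps between tiers of
    families.
    """
    if library.n_pairs == 0:
        raise InvalidParameterError("empty read library")
    rng = np.random.default_rng(config.seed)
    catalog: list[MinedMonomer] = []
    log: list[IterationLog] = []
    remaining = library
    empty_streak = 0
    for it in range(1, config.max_iterations + 1):
        want = config.start_pairs * 2 ** (it - 1)
        n = min(want, remaining.n_pairs)
        if n < config.min_cluster_size:
            break
        sample = sample_reads(remaining, n, seed=int(rng.integers(2**31 - 1)))
        clusters = cluster_reads(
            sample.reads(),
            k=config.k,
            min_shared_kmers=config.min_shared_kmers,
            min_cluster_size=config.min_cluster_size,
        )
        new: list[MinedMonomer] = []
        for cluster in clusters[: config.max_clusters_per_iteration]:
            mono = detect_tandem(
                cluster,
                min_period=config.min_period,
                max_period=config.max_period,
                score_threshold=config.score_threshold,
                min_support=config.min_support,
            )
            if mono is None:
                continue
            mono.iteration = it
            known = catalog + new
            if any(
                rotational_identity(mono.consensus, m.consensus) >= config.dedup_identity
                for m in known
            ):
                continue
            new.append(mono)
        subtracted = 0
        if new:
            catalog.extend(new)
            remaining, subtracted = subtract_reads(
                remaining,
                new,
                min_identity=config.subtract_min_identity,
                min_cov=config.subtract_min_cov,
            )
        log.append(
            IterationLog(
                iteration=it,
                sample_pairs=n,
                clusters=len(clusters),
                new_monomers=len(new),
                pairs_subtracted=subtracted,
                pairs_remaining=remaining.n_pairs,
            )
        )
        if new:
            empty_streak = 0
        else:
            empty_streak += 1
            if empty_streak >= config.stop_after_empty:
                break
            if n >= remaining.n_pairs:
                break  # already sampling the whole library; doubling is moot
    return MiningResult(monomers=catalog, log=log)
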