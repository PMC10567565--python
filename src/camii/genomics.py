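"""Comparative-genomics statistics: HGT calling, networks, variant filters.

Horizontal gene transfer (HGT) shows up as near-identical sequence blocks
shared between genomes of different species, far beyond what their genome-
wide average nucleotide identity (ANI) would allow. Candidate blocks come
from an all-vs-all alignment screen (BLAST tabular input); each block gets a
p-value under an ANI null in which every aligned base matches independently
with probability equal to the genome pair's ANI, so

    p = P( Binomial(L, ani) >= round(identity * L) )

computed with the regularized incomplete beta function (numerically stable
for tiny tails). P-values are Benjamini-Hochberg adjusted over all blocks
jointly; a block is an HGT event when the adjusted p < 1e-5 and its length
exceeds 2,000 bp (strict). Species-pair HGT frequency is the fraction of
between-species genome pairs sharing at least one event. The module also
implements Gram-staining enrichment of HGT (Pearson chi-squared), reliable-
genotype and SNP-site filters, leaf-SNP proportion, genome QC gating and
single-linkage ANI species clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

logger = logging.getLogger(__name__)

HGT_ALPHA = 1e-5
HGT_MIN_LENGTH = 2000  # bp, strict: a 2,000 bp block fails
ANI_SPECIES_THRESHOLD = 0.95  # strict: same species iff ANI > 0.95

QC_MIN_COVERAGE = 20.0
QC_MIN_N50 = 5000.0
QC_MIN_COMPLETENESS = 80.0
QC_MAX_CONTAMINATION = 5.0

RELIABLE_MIN_DEPTH = 5
RELIABLE_MIN_HAPLOIDY = 0.9
SITE_MIN_RELIABLE_FRACTION = 0.9  # strict: exactly 0.9 is dropped


@dataclass
class AlignmentBlock:
    query: str
    subject: str
    length: int
    identity: float  # fraction in (0, 1]
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("block length must be > 0")
        if self.query == self.subject:
            raise ValueError("block genomes must be distinct")


def parse_blast_tab(path) -> list[AlignmentBlock]:
    """Parse 12-column tabular alignments (qseqid sseqid pident length ...).

    Percent identity is converted to a fraction; self-hits (query == subject)
    are dropped; malformed lines raise with their line number.
    """
    blocks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(parts)}"
                )
            try:
                q, s = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if q == s:
                continue
            blocks.append(
                AlignmentBlock(q, s, length, pident / 100.0, qstart, qend, sstart, send)
            )
    return blocks


def hgt_pvalue(length: int, identity: float, ani: float) -> float:
    """Tail probability of the observed identity under the ANI null.

    Null: each of the L aligned bases matches independently with probability
    ``ani``; p = P(X >= round(identity * L)) for X ~ Binomial(L, ani).
    """
    if not 0 < ani <= 1:
        raise ValueError("ani must be in (0, 1]")
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    if length <= 0:
        raise ValueError("length must be > 0")
    k = int(round(identity * length))
    if k <= 0:
        return 1.0
    # survival function P(X >= k) = P(X > k-1); stable via incomplete beta
    return float(sps.binom.sf(k - 1, length, ani))


def _ani_lookup(ani) -> callable:
    """Accept a square DataFrame, a tidy 3-column table, or a dict keyed by
    frozenset({a, b}); return lookup(a, b) -> float raising KeyError."""
    if isinstance(ani, pd.DataFrame):
        if ani.shape[1] == 3 and not isinstance(ani.index, pd.MultiIndex) and set(
            ani.columns
        ) != set(ani.index):
            cols = list(ani.columns)
            if {"ani"} <= set(cols) or ani.shape[1] == 3:
                table = {}
                for _, row in ani.iterrows():
                    a, b, v = row.iloc[0], row.iloc[1], float(row.iloc[2])
                    table[frozenset((a, b))] = v
                return lambda a, b: table[frozenset((a, b))]
        mat = ani

        def lookup(a, b):
            try:
                return float(mat.loc[a, b])
            except KeyError:
                raise KeyError(f"no ANI entry for genome pair ({a}, {b})") from None

        return lookup
    if isinstance(ani, dict):
        def lookup_d(a, b):
            key = frozenset((a, b))
            if key not in ani:
                raise KeyError(f"no ANI entry for genome pair ({a}, {b})")
            return float(ani[key])

        return lookup_d
    raise TypeError("ani must be a DataFrame or a dict keyed by genome pair")


@dataclass
class HgtCall:
    block: AlignmentBlock
    ani: float
    p_raw: float
    p_adjusted: float
    passed: bool


def call_hgt(
    blocks,
    ani,
    alpha: float = HGT_ALPHA,
    min_length: int = HGT_MIN_LENGTH,
) -> list[HgtCall]:
    """Score candidate blocks under the ANI null and call HGT events.

    Benjamini-Hochberg runs over all blocks jointly; a block passes iff its
    adjusted p < ``alpha`` and its length is strictly greater than
    ``min_length``.
    """
    if isinstance(blocks, pd.DataFrame):
        blocks = [
            AlignmentBlock(
                r["query"],
                r["subject"],
                int(r["length"]),
                float(r["identity"]),
                int(r.get("qstart", 0)),
                int(r.get("qend", 0)),
            )
            for _, r in blocks.iterrows()
        ]
    lookup = _ani_lookup(ani)
    anis = [lookup(b.query, b.subject) for b in blocks]
    raw = np.array([hgt_pvalue(b.length, b.identity, a) for b, a in zip(blocks, anis)])
    adj = bh_adjust(raw)
    return [
        HgtCall(
            block=b,
            ani=a,
            p_raw=float(pr),
            p_adjusted=float(pa),
            passed=bool(pa < alpha and b.length > min_length),
        )
        for b, a, pr, pa in zip(blocks, anis, raw, adj)
    ]


def calls_to_table(calls: list[HgtCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.block.query,
                c.block.subject,
                c.block.length,
                c.block.identity,
                c.ani,
                c.p_raw,
                c.p_adjusted,
                c.passed,
            )
            for c in calls
        ],
        columns=[
            "query",
            "subject",
            "length",
            "identity",
            "ani",
            "p_raw",
            "p_adjusted",
            "passed",
        ],
    )


def merge_blocks(calls: list[HgtCall]) -> dict[frozenset, list[tuple[int, int]]]:
    """Merge passing blocks of each genome pair by query-coordinate union.

    Overlapping or duplicate alignments between the same pair collapse into
    one interval, so one transfer event is not double-counted.
    """
    by_pair: dict[frozenset, list[tuple[int, int]]] = {}
    for c in calls:
        if not c.passed:
            continue
        key = frozenset((c.block.query, c.block.subject))
        lo, hi = sorted((c.block.qstart, c.block.qend))
        by_pair.setdefault(key, []).append((lo, hi))
    merged = {}
    for key, ivals in by_pair.items():
        ivals.sort()
        out = [list(ivals[0])]
        for lo, hi in ivals[1:]:
            if lo <= out[-1][1]:
                out[-1][1] = max(out[-1][1], hi)
            else:
                out.append([lo, hi])
        merged[key] = [tuple(iv) for iv in out]
    return merged


@dataclass
class HgtEdge:
    species_a: str
    species_b: str
    frequency: float
    n_pairs_sharing: int
    n_pairs_total: int
    category: str  # interphyla | intraphyla-interfamily | intrafamily


@dataclass
class HgtNetwork:
    edges: list[HgtEdge]
    high_frequency_fraction: float  # fraction of edges with frequency > 0.5

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    e.species_a,
                    e.species_b,
                    e.frequency,
                    e.n_pairs_sharing,
                    e.n_pairs_total,
                    e.category,
                )
                for e in self.edges
            ],
            columns=[
                "species_a",
                "species_b",
                "frequency",
                "n_pairs_sharing",
                "n_pairs_total",
                "category",
            ],
        )


def _category(tax_a: dict, tax_b: dict) -> str:
    if tax_a.get("phylum") != tax_b.get("phylum"):
        return "interphyla"
    if tax_a.get("family") == tax_b.get("family"):
        return "intrafamily"
    return "intraphyla-interfamily"


def hgt_frequency_network(
    calls: list[HgtCall],
    species_map: dict[str, str],
    taxonomy: dict[str, dict] | pd.DataFrame | None = None,
) -> HgtNetwork:
    """Species-pair HGT frequency: sharing genome pairs / total genome pairs.

    Each unordered species pair with at least one passing call contributes an
    edge; its frequency divides the number of genome pairs sharing >= 1 event
    by (genomes in A) x (genomes in B). Categories come from the family and
    phylum of the taxonomy map when supplied.
    """
    if isinstance(taxonomy, pd.DataFrame):
        taxonomy = taxonomy.set_index(taxonomy.columns[0]).to_dict(orient="index")
    genomes_by_species: dict[str, set] = {}
    for genome, sp in species_map.items():
        genomes_by_species.setdefault(sp, set()).add(genome)

    sharing: dict[tuple[str, str], set[frozenset]] = {}
    for c in calls:
        if not c.passed:
            continue
        for g in (c.block.query, c.block.subject):
            if g not in species_map:
                raise ValueError(f"genome {g!r} missing from the species map")
        sa, sb = species_map[c.block.query], species_map[c.block.subject]
        if sa == sb:
            continue  # within-species sharing is background, not HGT
        key = tuple(sorted((sa, sb)))
        sharing.setdefault(key, set()).add(
            frozenset((c.block.query, c.block.subject))
        )

    edges = []
    for (sa, sb), pairs in sorted(sharing.items()):
        total = len(genomes_by_species[sa]) * len(genomes_by_species[sb])
        cat = (
            _category(taxonomy.get(sa, {}), taxonomy.get(sb, {}))
            if taxonomy
            else "unknown"
        )
        edges.append(
            HgtEdge(
                species_a=sa,
                species_b=sb,
                frequency=len(pairs) / total,
                n_pairs_sharing=len(pairs),
                n_pairs_total=total,
                category=cat,
            )
        )
    high = (
        float(np.mean([e.frequency > 0.5 for e in edges])) if edges else float("nan")
    )
    return HgtNetwork(edges=edges, high_frequency_fraction=high)


def gram_enrichment(
    edges: list[HgtEdge], gram_map: dict[str, str]
) -> tuple[float, float, pd.DataFrame, np.ndarray]:
    """Pearson chi-squared: HGT presence/absence vs same/different Gram stain.

    The universe of species pairs is every unordered pair of species in
    ``gram_map``; a pair has HGT when it appears among ``edges``. Continuity
    correction is off. Returns (chi2, p, contingency, expected counts).
    """
    species = sorted(gram_map)
    if len({gram_map[s] for s in species}) < 2:
        raise ValueError("need at least 2 Gram categories represented")
    has_hgt = {tuple(sorted((e.species_a, e.species_b))) for e in edges}
    table = np.zeros((2, 2), dtype=int)  # rows: HGT yes/no; cols: same/diff
    for a, b in combinations(species, 2):
        same = gram_map[a] == gram_map[b]
        row = 0 if (a, b) in has_hgt else 1
        col = 0 if same else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate contingency table (zero margin): {table.tolist()}")
    chi2, p, _, expected = sps.chi2_contingency(table, correction=False)
    contingency = pd.DataFrame(
        table,
        index=["hgt", "no_hgt"],
        columns=["same_gram", "different_gram"],
    )
    return float(chi2), float(p), contingency, expected


# ---------------------------------------------------------------------------
# genotype and genome filters
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Per-site, per-isolate genotype calls with read depth and haploidy."""

    alleles: pd.DataFrame  # sites x isolates, allele strings
    depth: pd.DataFrame  # sites x isolates, read depth
    haploidy: pd.DataFrame  # sites x isolates, fraction of reads on the call

    def __post_init__(self) -> None:
        if not (
            self.alleles.shape == self.depth.shape == self.haploidy.shape
        ):
            raise ValueError("alleles, depth and haploidy shapes differ")
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("negative read depth")
        h = self.haploidy.to_numpy(dtype=float)
        if ((h < 0) | (h > 1)).any():
            raise ValueError("haploidy must be in [0, 1]")


def filter_genotypes(
    matrix: GenotypeMatrix,
    min_depth: int = RELIABLE_MIN_DEPTH,
    min_haploidy: float = RELIABLE_MIN_HAPLOIDY,
    min_reliable_fraction: float = SITE_MIN_RELIABLE_FRACTION,
) -> tuple[pd.DataFrame, list]:
    """Reliable-genotype mask and the SNP sites retained for analysis.

    A cell is reliable iff depth >= 5 and haploidy >= 0.9 (inclusive); a site
    is retained iff its reliable fraction is strictly greater than 0.9.
    """
    if matrix.alleles.empty:
        raise ValueError("empty genotype matrix")
    reliable = (matrix.depth >= min_depth) & (matrix.haploidy >= min_haploidy)
    frac = reliable.mean(axis=1)
    retained = list(frac.index[frac > min_reliable_fraction])
    return reliable, retained


def leaf_snp_proportion(
    alleles: pd.DataFrame,
    retained_sites: list | None = None,
    reliable: pd.DataFrame | None = None,
) -> float:
    """Fraction of retained SNP sites whose minor allele sits in one isolate.

    A site is a leaf SNP when all of its non-majority calls belong to exactly
    one isolate. Returns NaN (with a logged warning) for zero retained sites.
    """
    if alleles.shape[1] < 2:
        raise ValueError("need at least 2 isolates")
    sites = alleles.index if retained_sites is None else retained_sites
    if len(sites) == 0:
        logger.warning("zero retained sites; leaf-SNP proportion undefined")
        return float("nan")
    n_leaf = 0
    n_snp = 0
    for site in sites:
        calls = alleles.loc[site]
        if reliable is not None:
            calls = calls[reliable.loc[site]]
        counts = calls.value_counts()
        if len(counts) < 2:
            continue  # monomorphic among reliable calls: not a SNP
        n_snp += 1
        if counts.iloc[1:].sum() == 1:
            n_leaf += 1
    if n_snp == 0:
        logger.warning("no polymorphic retained sites; leaf-SNP proportion undefined")
        return float("nan")
    return n_leaf / n_snp


def genome_qc_filter(qc: pd.DataFrame) -> pd.Series:
    """High-quality draft genome gate, all inequalities strict:
    coverage > 20x, N50 > 5,000 bp, completeness > 80%, contamination < 5%.
    """
    required = ["coverage", "n50", "completeness", "contamination"]
    for genome, row in qc.iterrows():
        for metric in required:
            if metric not in row or pd.isna(row[metric]):
                raise ValueError(f"genome {genome!r}: missing metric {metric!r}")
    passed = (
        (qc["coverage"] > QC_MIN_COVERAGE)
        & (qc["n50"] > QC_MIN_N50)
        & (qc["completeness"] > QC_MIN_COMPLETENESS)
        & (qc["contamination"] < QC_MAX_CONTAMINATION)
    )
    passed.name = "passed"
    return passed


def species_cluster_by_ani(
    ani: pd.DataFrame, threshold: float = ANI_SPECIES_THRESHOLD
) -> pd.Series:
    """Single-linkage species clusters over edges with ANI > threshold.

    Transitivity is deliberate: a chain A-B-C above threshold is one cluster
    even when ANI(A, C) falls below it. Labels are integers ordered by each
    cluster's first genome.
    """
    mat = ani.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("ANI matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("ANI matrix asymmetric beyond tolerance")
    n = mat.shape[0]
    adj = mat > threshold
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = nxt
        while stack:
            u = stack.pop()
            for v in np.nonzero(adj[u])[0]:
                if labels[v] < 0:
                    labels[v] = nxt
                    stack.append(v)
        nxt += 1
    return pd.Series(labels, index=ani.index, name="species_cluster")
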