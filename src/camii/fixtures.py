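"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: plate image pairs
with a known colony layout, labelled morphology feature tables, spatial
communities with planted genus-genus growth interactions, colinear genome
sets with planted horizontally transferred blocks, and isolate/bulk ASV count
tables with a planted dominant ASV per isolate.

All generators are deterministic given their seed, and each returns its
ground truth alongside the artifact so downstream modules can be scored
without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imaging import MORPHOLOGY_FEATURES

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# plate images
# ---------------------------------------------------------------------------


@dataclass
class ColonyBlueprint:
    x: float
    y: float
    radius_px: float
    peak_intensity: float = 150.0
    rgb_color: tuple[float, float, float] = (200.0, 160.0, 120.0)
    shape: str = "disk"  # disk | ellipse | irregular


@dataclass
class PlateSpec:
    """Layout of a synthetic plate: geometry, colonies, optics noise."""

    width_px: int = 512
    height_px: int = 512
    plate_margin_px: int = 20
    colonies: list[ColonyBlueprint] = field(default_factory=list)
    background_level: float = 30.0
    noise_sd: float = 2.0
    blur_sigma: float = 0.8
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("plate dimensions must be positive")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        cols = []
        for c in self.colonies:
            if not isinstance(c, ColonyBlueprint):
                c = ColonyBlueprint(*c)
            if c.radius_px < 1:
                raise ValueError(f"colony radius must be >= 1 px (got {c.radius_px})")
            m = self.plate_margin_px
            if not (m <= c.x < self.width_px - m and m <= c.y < self.height_px - m):
                raise ValueError(
                    f"colony center ({c.x}, {c.y}) outside plate margin {m}"
                )
            cols.append(c)
        self.colonies = cols
        if not self.allow_overlap:
            for i in range(len(cols)):
                for j in range(i + 1, len(cols)):
                    a, b = cols[i], cols[j]
                    if a.shape == b.shape == "disk":
                        d = np.hypot(a.x - b.x, a.y - b.y)
                        if d < a.radius_px + b.radius_px:
                            raise ValueError(
                                f"colonies {i} and {j} overlap "
                                f"(distance {d:.1f} < {a.radius_px + b.radius_px:.1f})"
                            )


_EDGE_HALF_WIDTH = 0.25  # px; linear intensity ramp centered on the radius


def _colony_profile(c: ColonyBlueprint, spec: PlateSpec, rng: np.random.Generator):
    """Coverage map (0..1) of one colony on its bounding box."""
    pad = int(np.ceil(c.radius_px * 1.6 + 3))
    x0, x1 = int(c.x) - pad, int(c.x) + pad + 1
    y0, y1 = int(c.y) - pad, int(c.y) + pad + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - c.x, yy - c.y
    if c.shape == "ellipse":
        elong = 1.4
        d = np.hypot(dx / elong, dy * elong)
        r_eff = np.full_like(d, c.radius_px)
    elif c.shape == "irregular":
        theta = np.arctan2(dy, dx)
        d = np.hypot(dx, dy)
        r_eff = np.full_like(d, c.radius_px)
        for k in (2, 3, 4):
            amp = 0.06 * c.radius_px * rng.uniform(0.5, 1.0)
            phase = rng.uniform(0, 2 * np.pi)
            r_eff = r_eff + amp * np.cos(k * theta + phase)
    else:  # disk
        d = np.hypot(dx, dy)
        r_eff = np.full_like(d, c.radius_px)
    e = _EDGE_HALF_WIDTH
    cov = np.clip((r_eff + e - d) / (2 * e), 0.0, 1.0)
    return (y0, y1, x0, x1), cov


def generate_plate(spec: PlateSpec):
    """Render one plate: (trans uint8 image, epi uint8 RGB image, truth table).

    Colonies are drawn as plateau blobs with a sub-pixel edge ramp, optionally
    Gaussian-blurred, then additive Gaussian noise is applied. The truth table
    lists every colony's center, radius, shape and nominal area (pi r^2).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    trans = np.full((h, w), float(spec.background_level))
    epi = np.full((h, w, 3), 10.0)

    truth_rows = []
    for i, c in enumerate(spec.colonies):
        (y0, y1, x0, x1), cov = _colony_profile(c, spec, rng)
        ys = slice(max(y0, 0), min(y1, h))
        xs = slice(max(x0, 0), min(x1, w))
        cys = slice(ys.start - y0, ys.stop - y0)
        cxs = slice(xs.start - x0, xs.stop - x0)
        patch = cov[cys, cxs]
        trans[ys, xs] = np.maximum(trans[ys, xs], spec.background_level + c.peak_intensity * patch)
        for ch in range(3):
            epi[ys, xs, ch] = epi[ys, xs, ch] * (1 - patch) + c.rgb_color[ch] * patch
        truth_rows.append(
            {
                "colony_id": f"truth_{i:04d}",
                "x_px": c.x,
                "y_px": c.y,
                "radius_px": c.radius_px,
                "shape": c.shape,
                "area_px2": np.pi * c.radius_px**2,
            }
        )

    if spec.blur_sigma > 0:
        trans = ndi.gaussian_filter(trans, spec.blur_sigma)
        epi = ndi.gaussian_filter(epi, (spec.blur_sigma, spec.blur_sigma, 0))
    if spec.noise_sd > 0:
        trans = trans + rng.normal(0, spec.noise_sd, trans.shape)
        epi = epi + rng.normal(0, spec.noise_sd, epi.shape)

    trans8 = np.clip(np.round(trans), 0, 255).astype(np.uint8)
    epi8 = np.clip(np.round(epi), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        truth_rows,
        columns=["colony_id", "x_px", "y_px", "radius_px", "shape", "area_px2"],
    )
    return trans8, epi8, truth


def random_plate_spec(
    n_colonies: int,
    seed: int,
    width_px: int = 512,
    height_px: int = 512,
    radius_range: tuple[float, float] = (8.0, 15.0),
    min_edge_separation: float = 5.0,
    noise_sd: float = 2.0,
    **kwargs,
) -> PlateSpec:
    """A plate of non-overlapping random disks with edge gaps >= separation."""
    rng = np.random.default_rng(seed)
    margin = kwargs.pop("plate_margin_px", 20)
    placed: list[ColonyBlueprint] = []
    attempts = 0
    while len(placed) < n_colonies:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError(
                f"could not place {n_colonies} colonies after {attempts} attempts"
            )
        r = rng.uniform(*radius_range)
        x = rng.uniform(margin + r + 2, width_px - margin - r - 2)
        y = rng.uniform(margin + r + 2, height_px - margin - r - 2)
        ok = all(
            np.hypot(x - c.x, y - c.y) >= r + c.radius_px + min_edge_separation
            for c in placed
        )
        if ok:
            placed.append(
                ColonyBlueprint(
                    x=x,
                    y=y,
                    radius_px=r,
                    peak_intensity=rng.uniform(120, 200),
                    rgb_color=tuple(rng.uniform(80, 230, 3)),
                    shape="disk",
                )
            )
    return PlateSpec(
        width_px=width_px,
        height_px=height_px,
        plate_margin_px=margin,
        colonies=placed,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# labelled morphology tables
# ---------------------------------------------------------------------------


@dataclass
class GenusProfile:
    name: str
    mean: np.ndarray  # length 14
    cov: np.ndarray | float  # 14x14 covariance or scalar variance
    base_colony_radius: float = 10.0
    abundance: float = 1.0


def generate_morphology_dataset(
    profiles: list[GenusProfile],
    n_per_genus: int,
    seed: int,
    conditions: tuple[str, ...] = ("mGAM",),
) -> pd.DataFrame:
    """Labelled feature table: 14 Gaussian features + condition + neighbor count.

    Each genus contributes ``n_per_genus`` rows drawn from its multivariate
    Gaussian morphology profile. The antibiotic condition is sampled uniformly
    from ``conditions`` and the nearby-colony count from Poisson(2), matching
    the covariates carried by real colony tables.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genus profiles")
    rng = np.random.default_rng(seed)
    frames = []
    for prof in profiles:
        mean = np.asarray(prof.mean, dtype=float)
        if mean.shape != (14,):
            raise ValueError(f"{prof.name}: mean must have length 14")
        cov = prof.cov
        if np.isscalar(cov):
            cov = np.eye(14) * float(cov)
        cov = np.asarray(cov, dtype=float)
        if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
            raise ValueError(f"{prof.name}: covariance is not positive semi-definite")
        if n_per_genus > 0:
            X = rng.multivariate_normal(mean, cov, size=n_per_genus, method="cholesky" if np.min(np.linalg.eigvalsh(cov)) > 1e-12 else "svd")
        else:
            X = np.empty((0, 14))
        df = pd.DataFrame(X, columns=MORPHOLOGY_FEATURES)
        df["condition"] = rng.choice(list(conditions), size=len(df))
        df["n_neighbors"] = rng.poisson(2.0, size=len(df))
        df["genus"] = prof.name
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# spatial communities with planted interactions
# ---------------------------------------------------------------------------


@dataclass
class Interaction:
    source: str
    target: str
    fold_effect: float  # 1.0 means no interaction

    def __post_init__(self) -> None:
        if self.fold_effect <= 0:
            raise ValueError("fold_effect must be > 0")


@dataclass
class CommunitySpec:
    """Planted spatial community: genus mix, geometry and growth interactions."""

    genera: list[GenusProfile]
    interactions: list[Interaction] = field(default_factory=list)
    n_colonies: int = 500
    neighbor_slack_px: float = 30.0
    width_px: int = 2560
    height_px: int = 2560
    lognormal_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.interactions = [
            i if isinstance(i, Interaction) else Interaction(*i)
            for i in self.interactions
        ]
        weights = np.array([g.abundance for g in self.genera], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("abundance weights must sum to a positive value")
        self._weights = weights / weights.sum()


def generate_spatial_community(spec: CommunitySpec):
    """Place colonies and apply planted neighbor growth effects.

    Colonies are placed uniformly at random with rejection sampling (minimum
    center separation = sum of radii + 2 px). Each colony's area is its genus
    base area (pi r^2) times the fold effect of every interaction whose source
    genus is present among its neighbors (30 px + radii rule), times
    multiplicative lognormal noise. Returns (colony table, interaction truth).
    """
    rng = np.random.default_rng(spec.seed)
    names = [g.name for g in spec.genera]
    radii = {g.name: g.base_colony_radius for g in spec.genera}
    genus_of = rng.choice(names, size=spec.n_colonies, p=spec._weights)

    max_r = max(radii.values())
    cell = 2 * max_r + 2
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(spec.n_colonies)
    ys = np.empty(spec.n_colonies)
    rs = np.array([radii[g] for g in genus_of])
    for i in range(spec.n_colonies):
        r = rs[i]
        placed = False
        for _ in range(500):
            x = rng.uniform(r + 2, spec.width_px - r - 2)
            y = rng.uniform(r + 2, spec.height_px - r - 2)
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for ax in range(gx - 1, gx + 2):
                for ay in range(gy - 1, gy + 2):
                    for j in grid.get((ax, ay), ()):
                        if np.hypot(x - xs[j], y - ys[j]) < r + rs[j] + 2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                xs[i], ys[i] = x, y
                grid.setdefault((gx, gy), []).append(i)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place colony {i} of {spec.n_colonies} without overlap; "
                "reduce n_colonies or enlarge the plate"
            )

    # neighbor sets under the 30 px + radii rule
    slack = spec.neighbor_slack_px
    neighbor_genera: list[set[str]] = [set() for _ in range(spec.n_colonies)]
    n_neighbors = np.zeros(spec.n_colonies, dtype=int)
    reach = slack + 2 * max_r
    for i in range(spec.n_colonies):
        gx, gy = int(xs[i] // cell), int(ys[i] // cell)
        span = int(np.ceil(reach / cell)) + 1
        for ax in range(gx - span, gx + span + 1):
            for ay in range(gy - span, gy + span + 1):
                for j in grid.get((ax, ay), ()):
                    if j <= i:
                        continue
                    if np.hypot(xs[i] - xs[j], ys[i] - ys[j]) < slack + rs[i] + rs[j]:
                        neighbor_genera[i].add(genus_of[j])
                        neighbor_genera[j].add(genus_of[i])
                        n_neighbors[i] += 1
                        n_neighbors[j] += 1

    fold = {(it.source, it.target): it.fold_effect for it in spec.interactions}
    areas = np.pi * rs**2
    for i in range(spec.n_colonies):
        for src in neighbor_genera[i]:
            f = fold.get((src, genus_of[i]))
            if f is not None:
                areas[i] *= f
    areas *= np.exp(rng.normal(0.0, spec.lognormal_sigma, spec.n_colonies))

    table = pd.DataFrame(
        {
            "colony_id": [f"c{i:05d}" for i in range(spec.n_colonies)],
            "plate_barcode": "SIM0",
            "x_px": xs,
            "y_px": ys,
            "radius_px": rs,
            "area_px2": areas,
            "n_neighbors": n_neighbors,
            "genus": genus_of,
            "condition": "mGAM",
        }
    )
    truth = pd.DataFrame(
        [(it.source, it.target, it.fold_effect) for it in spec.interactions],
        columns=["source", "target", "fold_effect"],
    )
    return table, truth


# ---------------------------------------------------------------------------
# genomes with planted HGT blocks
# ---------------------------------------------------------------------------


@dataclass
class PlantedBlock:
    species_a: str
    species_b: str
    length_bp: int
    identity: float

    def __post_init__(self) -> None:
        if not 0 < self.identity <= 1:
            raise ValueError("identity must be in (0, 1]")


@dataclass
class HgtScenario:
    """Colinear genome set: species at a common background ANI, plus planted
    high-identity blocks copied between the first genome of each species pair.
    """

    genome_length_bp: int = 50_000
    n_species: int = 2
    genomes_per_species: int = 2
    background_ani: float = 0.90
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    within_species_divergence: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_ani <= 1:
            raise ValueError("background_ani must be in (0, 1]")
        self.planted_blocks = [
            b if isinstance(b, PlantedBlock) else PlantedBlock(*b)
            for b in self.planted_blocks
        ]
        for b in self.planted_blocks:
            if b.length_bp > self.genome_length_bp:
                raise ValueError("planted block longer than genome")


@dataclass
class HgtGenomeSet:
    genomes: dict[str, str]
    species_map: dict[str, str]
    planted: pd.DataFrame  # genome_a, genome_b, start, length_bp, identity
    ani: pd.DataFrame  # square matrix of measured pairwise identities
    warnings: list[str]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        out[hits] = (out[hits] + shift) % 4
    return out


def _divergence_rate(ani: float) -> float:
    """Per-lineage substitution rate p so two lineages mutated independently
    from a common ancestor match with probability ``ani``:
    (1-p)^2 + p^2/3 = ani."""
    # (4/3) p^2 - 2 p + (1 - ani) = 0
    disc = 4.0 - (16.0 / 3.0) * (1.0 - ani)
    return float((2.0 - np.sqrt(disc)) / (8.0 / 3.0))


def generate_hgt_genomes(scenario: HgtScenario) -> HgtGenomeSet:
    """Generate colinear genomes at a target background ANI with planted blocks.

    All genomes share coordinates with a single random ancestor (i.i.d.
    substitutions, no indels), so window-to-window comparison at equal
    coordinates is a valid alignment. Planted blocks are copied from the first
    genome of the source species into the first genome of the target species
    at a random recorded coordinate, mutated to the stated identity.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.genome_length_bp
    root = rng.integers(0, 4, size=L)
    p = _divergence_rate(scenario.background_ani)

    species = [f"S{i + 1}" for i in range(scenario.n_species)]
    species_seq = {s: _mutate(root, p, rng) for s in species}
    genomes: dict[str, np.ndarray] = {}
    species_map: dict[str, str] = {}
    for s in species:
        for g in range(scenario.genomes_per_species):
            name = f"{s}_g{g}"
            genomes[name] = _mutate(species_seq[s], scenario.within_species_divergence, rng)
            species_map[name] = s

    warns: list[str] = []
    planted_rows = []
    for b in scenario.planted_blocks:
        if scenario.background_ani >= b.identity:
            msg = (
                f"planted block {b.species_a}->{b.species_b} identity "
                f"{b.identity} <= background ANI {scenario.background_ani}: "
                "indistinguishable from background"
            )
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
        ga, gb = f"{b.species_a}_g0", f"{b.species_b}_g0"
        if ga not in genomes or gb not in genomes:
            raise ValueError(f"planted block references unknown species pair {b.species_a}, {b.species_b}")
        start = int(rng.integers(0, L - b.length_bp + 1))
        donor = genomes[ga][start : start + b.length_bp]
        copied = _mutate(donor, 1.0 - b.identity, rng)
        genomes[gb] = genomes[gb].copy()
        genomes[gb][start : start + b.length_bp] = copied
        realized = float(np.mean(genomes[ga][start : start + b.length_bp] == copied))
        planted_rows.append((ga, gb, start, b.length_bp, realized))

    names = list(genomes)
    ani = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            bN = names[j]
            ident = float(np.mean(genomes[a] == genomes[bN]))
            ani.iloc[i, j] = ani.iloc[j, i] = ident

    genome_strs = {n: "".join(_BASES[v]) for n, v in genomes.items()}
    planted = pd.DataFrame(
        planted_rows, columns=["genome_a", "genome_b", "start", "length_bp", "identity"]
    )
    return HgtGenomeSet(genome_strs, species_map, planted, ani, warns)


def candidate_blocks_from_genomes(
    genome_set: HgtGenomeSet,
    n_random_blocks: int = 20,
    random_block_length: int = 2_500,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for an all-vs-all alignment screen.

    Because the generated genomes are colinear and indel-free, shared blocks
    can be read off by direct window comparison at equal coordinates: every
    planted block plus ``n_random_blocks`` random background windows per
    inter-species genome pair, each with its measured identity. Returns a
    table in the alignment-block layout consumed by ``camii.genomics``.
    """
    rng = np.random.default_rng(seed)
    seqs = {n: np.frombuffer(s.encode(), dtype=np.uint8) for n, s in genome_set.genomes.items()}
    rows = []

    def window_identity(a: str, b: str, start: int, length: int) -> float:
        return float(np.mean(seqs[a][start : start + length] == seqs[b][start : start + length]))

    for _, p in genome_set.planted.iterrows():
        ident = window_identity(p.genome_a, p.genome_b, int(p.start), int(p.length_bp))
        rows.append(
            (p.genome_a, p.genome_b, int(p.length_bp), ident, int(p.start) + 1, int(p.start) + int(p.length_bp))
        )

    names = sorted(seqs)
    L = len(next(iter(seqs.values())))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if genome_set.species_map[a] == genome_set.species_map[b]:
                continue
            for _ in range(n_random_blocks):
                length = min(random_block_length, L)
                start = int(rng.integers(0, L - length + 1))
                ident = window_identity(a, b, start, length)
                rows.append((a, b, length, ident, start + 1, start + length))
    return pd.DataFrame(
        rows, columns=["query", "subject", "length", "identity", "qstart", "qend"]
    )


def write_fasta(genomes: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=n, description="") for n, s in genomes.items()]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# ASV count tables
# ---------------------------------------------------------------------------


def generate_asv_table(
    n_isolates: int,
    asv_pool: list[str],
    purity_model: str | float = "pure",
    total_reads: int = 100,
    bulk_depth: int = 100_000,
    seed: int = 0,
):
    """Isolate x ASV count table plus a bulk abundance table.

    Each isolate receives a planted dominant ASV drawn from the bulk
    abundance distribution (lognormal weights over the pool, i.e. long-tailed).
    ``purity_model`` is either ``"pure"`` (all reads on the dominant ASV) or a
    float dominant fraction f: counts ~ Multinomial(total_reads, f on the
    dominant ASV, (1-f) spread evenly over the rest).

    Returns (counts DataFrame, truth Series isolate -> planted ASV,
    bulk abundance Series summing to 1).
    """
    if len(asv_pool) == 0:
        raise ValueError("ASV pool is empty")
    rng = np.random.default_rng(seed)
    pool = list(asv_pool)
    weights = np.exp(rng.normal(0.0, 1.5, size=len(pool)))
    bulk_p = weights / weights.sum()
    bulk_counts = rng.multinomial(bulk_depth, bulk_p)
    bulk = pd.Series(bulk_counts / bulk_counts.sum(), index=pool, name="abundance")

    counts = np.zeros((n_isolates, len(pool)), dtype=int)
    dominants = rng.choice(len(pool), size=n_isolates, p=bulk_p)
    for i in range(n_isolates):
        d = dominants[i]
        if purity_model == "pure":
            counts[i, d] = total_reads
        else:
            f = float(purity_model)
            if not 0 < f <= 1:
                raise ValueError("dominant fraction must be in (0, 1]")
            probs = np.full(len(pool), (1.0 - f) / max(len(pool) - 1, 1))
            probs[d] = f if len(pool) > 1 else 1.0
            counts[i] = rng.multinomial(total_reads, probs)
    table = pd.DataFrame(
        counts, index=[f"iso{i:04d}" for i in range(n_isolates)], columns=pool
    )
    table.index.name = "isolate_id"
    truth = pd.Series(
        [pool[d] for d in dominants], index=table.index, name="planted_asv"
    )
    return table, truth, bulk
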