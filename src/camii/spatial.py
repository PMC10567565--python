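"""Colony neighborhood statistics: crowding, genus-genus interactions, kinetics.

Two colonies are neighbors when their center distance is shorter than 30
pixels plus the sum of their radii. Crowding compares colony areas between
sparse (<=1 neighbor) and crowded (>=4 neighbors) groups by a one-sided
Mann-Whitney U test. The directed genus-genus interaction network compares,
for every ordered pair (A, B), the sizes of B colonies having at least one A
neighbor against B colonies with no neighbors of any genus: the effect size
is the fold-change of mean colony size, and p-values are Holm-adjusted across
all conducted tests. Daily growth kinetics track colonies across imaging days
by nearest-centroid matching and summarise, per genus, the proportion of
final-day colonies already detectable on each earlier day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .stats import holm_adjust, mann_whitney

logger = logging.getLogger(__name__)

NEIGHBOR_SLACK_PX = 30.0


def build_neighbor_graph(colonies: pd.DataFrame, slack: float = NEIGHBOR_SLACK_PX) -> nx.Graph:
    """Undirected neighbor graph under the distance < slack + r_i + r_j rule.

    Edges are computed within each plate only. Node attributes carry genus
    (when present) and neighbor counts.
    """
    required = {"colony_id", "x_px", "y_px", "radius_px"}
    missing = required - set(colonies.columns)
    if missing:
        raise KeyError(f"colony table missing column(s): {sorted(missing)}")
    if (colonies["radius_px"] <= 0).any():
        raise ValueError("radii must be > 0")
    graph = nx.Graph()
    plates = (
        colonies.groupby("plate_barcode")
        if "plate_barcode" in colonies.columns
        else [(None, colonies)]
    )
    for plate, df in plates:
        ids = df["colony_id"].astype(str).to_numpy()
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise ValueError(f"duplicate colony id {dup!r} on plate {plate!r}")
        pts = df[["x_px", "y_px"]].to_numpy(dtype=float)
        radii = df["radius_px"].to_numpy(dtype=float)
        for i, cid in enumerate(ids):
            attrs = {"plate": plate, "radius": radii[i]}
            if "genus" in df.columns:
                attrs["genus"] = df["genus"].iloc[i]
            graph.add_node(cid, **attrs)
        if len(df) < 2:
            continue
        tree = cKDTree(pts)
        rmax = radii.max()
        for i, j in tree.query_pairs(slack + 2 * rmax):
            d = np.hypot(*(pts[i] - pts[j]))
            if d < slack + radii[i] + radii[j]:
                graph.add_edge(ids[i], ids[j])
    for node in graph.nodes:
        graph.nodes[node]["n_neighbors"] = graph.degree(node)
    return graph


@dataclass
class CrowdingResult:
    p: float
    median_low: float
    median_high: float
    n_low: int
    n_high: int
    method: str


def crowding_test(
    areas,
    neighbor_counts,
    low_max: int = 1,
    high_min: int = 4,
    alternative: str = "greater",
) -> CrowdingResult:
    """One-sided Mann-Whitney U on areas of sparse vs crowded colonies.

    ``alternative="greater"`` tests whether crowded colonies (>= ``high_min``
    neighbors) are larger than sparse ones (<= ``low_max``); ``"less"`` tests
    the opposite direction.
    """
    areas = np.asarray(areas, dtype=float)
    counts = np.asarray(neighbor_counts)
    low = areas[counts <= low_max]
    high = areas[counts >= high_min]
    if low.size == 0:
        raise ValueError(f"empty low-crowding group (<= {low_max} neighbors)")
    if high.size == 0:
        raise ValueError(f"empty high-crowding group (>= {high_min} neighbors)")
    res = mann_whitney(high, low, alternative=alternative)
    return CrowdingResult(
        p=res.p,
        median_low=float(np.median(low)),
        median_high=float(np.median(high)),
        n_low=low.size,
        n_high=high.size,
        method=res.method,
    )


@dataclass
class InteractionEdge:
    source: str
    target: str
    effect_size: float  # fold-change of mean target size with source present
    direction: str  # "promoting" or "inhibiting"
    p_raw: float
    p_adjusted: float
    n_with: int
    n_without: int


def interaction_network(
    colonies: pd.DataFrame,
    slack: float = NEIGHBOR_SLACK_PX,
    min_group: int = 5,
    condition_filter: str | None = "mGAM",
    area_column: str = "area_px2",
) -> list[InteractionEdge]:
    """Directed genus-genus growth-interaction network.

    For each ordered genus pair (A, B): group 1 = B colonies with >= 1 A
    neighbor, group 2 = B colonies with zero neighbors of any genus. Effect
    size is mean(group1) / mean(group2); one-sided Mann-Whitney tests are run
    in both directions and the smaller p is reported with its sign
    ("promoting" when the with-A group is larger). Holm adjustment spans all
    conducted tests. Pairs with either group below ``min_group`` are skipped
    and logged. When a condition column is present only colonies from the
    antibiotic-free condition are used.
    """
    df = colonies.copy()
    if condition_filter is not None and "condition" in df.columns:
        df = df[df["condition"] == condition_filter]
    if "genus" not in df.columns:
        raise KeyError("colony table needs a 'genus' column")
    genera = sorted(df["genus"].dropna().unique())
    if len(genera) < 2:
        raise ValueError("need at least 2 genera")

    graph = build_neighbor_graph(df, slack=slack)
    df = df.set_index(df["colony_id"].astype(str))
    areas = df[area_column]
    genus_of = df["genus"]

    zero_neighbor = {n for n in graph.nodes if graph.degree(n) == 0}
    baseline = {
        g: areas[[n for n in zero_neighbor if genus_of[n] == g]].to_numpy()
        for g in genera
    }
    for g in genera:
        if baseline[g].size == 0:
            logger.warning(
                "genus %s has no zero-neighbor colonies; incoming edges skipped", g
            )

    tests = []  # (source, target, g1, g2)
    for target in genera:
        g2 = baseline[target]
        if g2.size < min_group:
            if 0 < g2.size:
                logger.info(
                    "skipping edges into %s: only %d zero-neighbor colonies",
                    target,
                    g2.size,
                )
            continue
        target_nodes = [n for n in graph.nodes if genus_of[n] == target]
        for source in genera:
            with_src = [
                n
                for n in target_nodes
                if any(genus_of[m] == source for m in graph.neighbors(n))
            ]
            g1 = areas[with_src].to_numpy()
            if g1.size < min_group:
                logger.info(
                    "skipping %s->%s: only %d colonies with a %s neighbor",
                    source,
                    target,
                    g1.size,
                    source,
                )
                continue
            tests.append((source, target, g1, g2))

    raw_p = []
    meta = []
    for source, target, g1, g2 in tests:
        p_greater = mann_whitney(g1, g2, alternative="greater").p
        p_less = mann_whitney(g1, g2, alternative="less").p
        raw_p.extend([p_greater, p_less])
        meta.append((source, target, g1, g2, p_greater, p_less))
    adjusted = holm_adjust(raw_p)

    edges = []
    for i, (source, target, g1, g2, p_g, p_l) in enumerate(meta):
        if p_g <= p_l:
            p_raw, p_adj, direction = p_g, adjusted[2 * i], "promoting"
        else:
            p_raw, p_adj, direction = p_l, adjusted[2 * i + 1], "inhibiting"
        edges.append(
            InteractionEdge(
                source=source,
                target=target,
                effect_size=float(g1.mean() / g2.mean()),
                direction=direction,
                p_raw=float(p_raw),
                p_adjusted=float(p_adj),
                n_with=g1.size,
                n_without=g2.size,
            )
        )
    return edges


def edges_to_table(edges: list[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                e.source,
                e.target,
                e.effect_size,
                e.direction,
                e.p_raw,
                e.p_adjusted,
                e.n_with,
                e.n_without,
            )
            for e in edges
        ],
        columns=[
            "source",
            "target",
            "effect_size",
            "direction",
            "p_raw",
            "p_adjusted",
            "n_with",
            "n_without",
        ],
    )


def edges_to_graph(edges: list[InteractionEdge]) -> nx.DiGraph:
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(
            e.source,
            e.target,
            effect_size=e.effect_size,
            direction=e.direction,
            p_raw=e.p_raw,
            p_adjusted=e.p_adjusted,
        )
    return g


# ---------------------------------------------------------------------------
# daily growth kinetics
# ---------------------------------------------------------------------------


@dataclass
class ColonyTrack:
    track_id: str
    first_day: int
    detections: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    colony_ids: dict[int, str] = field(default_factory=dict)

    @property
    def last_position(self) -> tuple[float, float]:
        d = max(self.detections)
        x, y, _ = self.detections[d]
        return x, y


def track_colonies(
    day_tables: list[pd.DataFrame], tolerance: float = 10.0
) -> list[ColonyTrack]:
    """Match colonies across imaging days by X-Y coordinates.

    ``day_tables`` must be ordered by strictly increasing ``day``. Matching
    is greedy nearest-centroid within ``tolerance`` pixels (closest pairs
    first, ties toward the lowest colony id); unmatched colonies on a later
    day start new tracks, and no colony is matched twice on one day.
    """
    days = []
    for t in day_tables:
        if "day" not in t.columns or t["day"].nunique() > 1:
            raise ValueError("each day table must carry a single 'day' value")
        days.append(int(t["day"].iloc[0]) if len(t) else None)
    known = [d for d in days if d is not None]
    if known != sorted(known) or len(set(known)) != len(known):
        raise ValueError(f"day tables out of order: {days}")

    tracks: list[ColonyTrack] = []
    area_col = None
    for table in day_tables:
        if len(table) == 0:
            continue
        if area_col is None:
            area_col = "area_px2" if "area_px2" in table.columns else None
        day = int(table["day"].iloc[0])
        new_ids = table["colony_id"].astype(str).to_numpy()
        xs = table["x_px"].to_numpy(dtype=float)
        ys = table["y_px"].to_numpy(dtype=float)
        areas = (
            table[area_col].to_numpy(dtype=float)
            if area_col
            else np.full(len(table), np.nan)
        )

        candidates = []
        for ti, tr in enumerate(tracks):
            tx, ty = tr.last_position
            for ci in range(len(table)):
                d = np.hypot(xs[ci] - tx, ys[ci] - ty)
                if d <= tolerance:
                    candidates.append((d, new_ids[ci], ti, ci))
        candidates.sort(key=lambda t: (t[0], t[1]))
        used_tracks: set[int] = set()
        used_colonies: set[int] = set()
        for d, _, ti, ci in candidates:
            if ti in used_tracks or ci in used_colonies:
                continue
            tracks[ti].detections[day] = (xs[ci], ys[ci], areas[ci])
            tracks[ti].colony_ids[day] = new_ids[ci]
            used_tracks.add(ti)
            used_colonies.add(ci)
        for ci in range(len(table)):
            if ci not in used_colonies:
                tr = ColonyTrack(track_id=f"t{len(tracks):05d}", first_day=day)
                tr.detections[day] = (xs[ci], ys[ci], areas[ci])
                tr.colony_ids[day] = new_ids[ci]
                tracks.append(tr)
    return tracks


def detectable_proportion(
    tracks: list[ColonyTrack], labels
) -> pd.DataFrame:
    """Genus x day matrix of the detectable proportion relative to the final day.

    Entry (g, d) = number of genus-g tracks first detected on day <= d,
    divided by the genus's total number of final-day tracks. Labels are keyed
    by the final-day colony id. Genera with zero final-day colonies are
    omitted with a logged warning. Rows are non-decreasing and end at 1.
    """
    labels = dict(labels) if not isinstance(labels, dict) else labels
    if not tracks:
        raise ValueError("no tracks")
    all_days = sorted({d for tr in tracks for d in tr.detections})
    final_day = all_days[-1]

    by_genus: dict[str, list[ColonyTrack]] = {}
    for tr in tracks:
        if final_day not in tr.detections:
            continue
        cid = tr.colony_ids[final_day]
        if cid not in labels:
            raise ValueError(f"final-day colony {cid!r} has no genus label")
        by_genus.setdefault(labels[cid], []).append(tr)

    rows = {}
    for genus in sorted(by_genus):
        trs = by_genus[genus]
        if not trs:
            logger.warning("genus %s has zero final-day colonies; row omitted", genus)
            continue
        denom = len(trs)
        rows[genus] = [
            sum(tr.first_day <= d for tr in trs) / denom for d in all_days
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_days)
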