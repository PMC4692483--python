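"""Homotypic cluster detection, enrichment scoring, filtering and ranking.

A candidate cluster is any run of 3-10 consecutive binding sites whose
end-to-end span (outside ends of the flanking sites) is at most 1000 bp.
Its clustering coefficient (CC) is the observed site count divided by
the mean count of background sites fully contained in the same interval
across the composition-corrected background replicates.  Reported
clusters must pass, in flag order: CC >= 4, at least one member site
with MSS >= 0.81, no member site overlapping an exon or repeat interval,
and member sites covering at most 25% of the span.  Pass/fail is a
conjunction; the order only affects flag readability.  Overlapping
passing windows that share a member site are merged and represented by
the window with the most sites (ties: higher average MSS, then leftmost
start); the final report is ranked by average MSS, high to low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .annotation import IntervalSet
from .background import BackgroundEnsemble
from .genome import BindingSite

log = logging.getLogger(__name__)

FILTER_NAMES = ("cc", "anchor_mss", "exon", "repeat", "site_fraction")


@dataclass
class ClusterConfig:
    """Cluster-detection thresholds (defaults are the standard cascade)."""

    min_sites: int = 3
    max_sites: int = 10
    max_span: int = 1000
    cc_min: float = 4.0
    anchor_mss: float = 0.81
    site_fraction_max: float = 0.25
    expected_floor: float | None = None  # default: 1 / n_replicates

    def __post_init__(self) -> None:
        if self.min_sites < 2:
            raise ValueError("min_sites must be >= 2")
        if self.min_sites > self.max_sites:
            raise ValueError("min_sites must not exceed max_sites")
        if self.max_span <= 0 or self.cc_min <= 0:
            raise ValueError("max_span and cc_min must be positive")


@dataclass
class Cluster:
    """A window of consecutive sites with its scores, flags and member list.

    first_index is the offset of the first member in the per-chromosome
    sorted site list; windows share a member site iff their index ranges
    overlap.
    """

    chrom: str
    start: int
    end: int
    sites: list[BindingSite]
    first_index: int
    expected_sites: float | None = None
    cc: float | None = None
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def avg_mss(self) -> float:
        return float(np.mean([s.mss for s in self.sites]))

    @property
    def max_mss(self) -> float:
        return float(max(s.mss for s in self.sites))

    @property
    def site_bp_fraction(self) -> float:
        """Union of member-site bases (overlap counted once) over the span."""
        covered = 0
        cur_s = cur_e = None
        for s in self.sites:
            if cur_e is None or s.start > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s.start, s.end
            else:
                cur_e = max(cur_e, s.end)
        if cur_e is not None:
            covered += cur_e - cur_s
        return covered / self.span

    @property
    def passed(self) -> bool:
        return bool(self.flags) and all(self.flags.values())

    def display_coords(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def enumerate_windows(sites: list[BindingSite], config: ClusterConfig) -> list[Cluster]:
    """Every window of min_sites..max_sites consecutive sites with span <= max_span.

    Sites must be sorted by start and belong to one chromosome.  The span
    boundary is inclusive: span == max_span passes.
    """
    if any(b.start < a.start for a, b in zip(sites, sites[1:])):
        raise ValueError("sites must be sorted by start")
    if len({s.chrom for s in sites}) > 1:
        raise ValueError("enumerate_windows expects sites from a single chromosome")
    out: list[Cluster] = []
    n = len(sites)
    for i in range(n):
        for k in range(config.min_sites, config.max_sites + 1):
            j = i + k - 1
            if j >= n:
                break
            start = sites[i].start
            end = max(s.end for s in sites[i : j + 1])  # robust to contained sites
            if end - start > config.max_span:
                break  # spans only grow with k
            out.append(Cluster(chrom=sites[i].chrom, start=start, end=end, sites=list(sites[i : j + 1]), first_index=i))
    return out


def expected_site_count(region: tuple[int, int], ensemble: BackgroundEnsemble, chrom: str | None = None) -> float:
    """Mean background site count fully contained in [start, end) across replicates."""
    if chrom is not None and chrom != ensemble.chrom:
        raise ValueError(f"region chromosome {chrom!r} not covered by ensemble for {ensemble.chrom!r}")
    return ensemble.expected_count(*region)


def cluster_coefficient(observed: int, expected: float, config: ClusterConfig, n_replicates: int | None = None) -> float:
    """CC = observed / max(expected, floor); floor defaults to 1/n_replicates."""
    if observed < 0 or expected < 0:
        raise ValueError("counts must be non-negative")
    floor = config.expected_floor
    if floor is None:
        if n_replicates is None:
            raise ValueError("need n_replicates to derive the default expected floor")
        floor = 1.0 / n_replicates
    return observed / max(expected, floor)


def score_clusters(clusters: list[Cluster], ensemble: BackgroundEnsemble, config: ClusterConfig) -> list[Cluster]:
    """Fill expected_sites and cc for every window against the ensemble."""
    for c in clusters:
        if c.chrom != ensemble.chrom:
            raise ValueError(f"cluster on {c.chrom!r} scored against ensemble for {ensemble.chrom!r}")
        c.expected_sites = ensemble.expected_count(c.start, c.end)
        c.cc = cluster_coefficient(c.n_sites, c.expected_sites, config, ensemble.n_replicates)
    return clusters


def apply_filters(
    clusters: list[Cluster],
    exons: IntervalSet | None,
    repeats: IntervalSet | None,
    config: ClusterConfig,
) -> list[Cluster]:
    """Flag every window against the filter cascade; nothing is dropped.

    A window passes iff CC >= cc_min, its best site reaches anchor_mss,
    no member site overlaps an exon or repeat interval by >= 1 bp, and
    member sites cover <= site_fraction_max of the span.
    """
    for c in clusters:
        if c.cc is None:
            raise ValueError("clusters must be scored before filtering")
        c.flags["cc"] = c.cc >= config.cc_min
        c.flags["anchor_mss"] = c.max_mss >= config.anchor_mss
        c.flags["exon"] = not _any_site_overlap(c, exons)
        c.flags["repeat"] = not _any_site_overlap(c, repeats)
        c.flags["site_fraction"] = c.site_bp_fraction <= config.site_fraction_max
    return clusters


def _any_site_overlap(cluster: Cluster, intervals: IntervalSet | None) -> bool:
    if intervals is None:
        return False
    return any(intervals.overlaps(s.chrom, s.start, s.end) for s in cluster.sites)


def merge_and_report(passing: list[Cluster]) -> list[Cluster]:
    """Group windows sharing >= 1 member site; report one window per group.

    Windows over consecutive sites share a member iff their member-index
    ranges overlap, so grouping reduces to merging overlapping index
    ranges.  The representative maximizes n_sites, then avg_mss, then
    has the leftmost start.  Groups with disjoint site sets stay separate.
    """
    if not passing:
        return []
    if len({c.chrom for c in passing}) > 1:
        raise ValueError("merge_and_report expects windows from a single chromosome")
    order = sorted(passing, key=lambda c: (c.first_index, c.first_index + c.n_sites))
    groups: list[list[Cluster]] = []
    group_end: int | None = None
    for c in order:
        if group_end is None or c.first_index >= group_end:
            groups.append([c])
            group_end = c.first_index + c.n_sites
        else:
            groups[-1].append(c)
            group_end = max(group_end, c.first_index + c.n_sites)
    reported = []
    for grp in groups:
        best = max(grp, key=lambda c: (c.n_sites, c.avg_mss, -c.start))
        reported.append(best)
    return reported


def rank_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Descending average MSS; ties by n_sites descending, then coordinate."""
    return sorted(clusters, key=lambda c: (-c.avg_mss, -c.n_sites, c.chrom, c.start))


def detect_clusters(
    sites: list[BindingSite],
    ensembles: dict[str, BackgroundEnsemble],
    config: ClusterConfig,
    exons: IntervalSet | None = None,
    repeats: IntervalSet | None = None,
) -> tuple[list[Cluster], list[Cluster]]:
    """Full per-assembly cascade: enumerate, score, filter, merge, rank.

    Returns (all candidate windows with flags, ranked reported clusters).
    """
    all_windows: list[Cluster] = []
    reported: list[Cluster] = []
    by_chrom: dict[str, list[BindingSite]] = {}
    for s in sorted(sites, key=lambda s: (s.chrom, s.start)):
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, chrom_sites in by_chrom.items():
        if chrom not in ensembles:
            raise ValueError(f"no background ensemble for chromosome {chrom!r}")
        windows = enumerate_windows(chrom_sites, config)
        score_clusters(windows, ensembles[chrom], config)
        apply_filters(windows, exons, repeats, config)
        all_windows.extend(windows)
        reported.extend(merge_and_report([c for c in windows if c.passed]))
    counts = {name: sum(1 for c in all_windows if not c.flags.get(name, True)) for name in FILTER_NAMES}
    log.info(
        "windows: %d candidates, %d reported after merge; failures per filter: %s",
        len(all_windows),
        len(reported),
        counts,
    )
    return all_windows, rank_clusters(reported)
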