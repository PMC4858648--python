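"""E/NE labeling of activation clusters from anatomical cluster reports.

A cluster report (one per ROI, emulating an xjView-style summary) lists the
anatomical regions a cluster overlaps, with voxel counts and maximum
Z-score per region. Regions in anatomically plausible language areas
(Broca's/Wernicke's territory: Brodmann 44/45/22, inferior and middle
frontal gyri, superior temporal gyrus) count as Expected; regions of
non-task-related activity (cerebellum, sub-gyral white matter, insula,
post-central, supramarginal and superior frontal gyri) count as
Non-Expected. A cluster straddling both is labelled by the entry with the
higher maximum Z; clusters below the minimum size (default 5 voxels) are
filtered out entirely.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from fmritex.errors import ClusterTooSmallError, UnlabelableError
from fmritex.volumes import E, NE

logger = logging.getLogger(__name__)

DEFAULT_EXPECTED_REGIONS = frozenset({
    "brodmann area 44",
    "brodmann area 45",
    "brodmann area 22",
    "inferior frontal gyrus",
    "middle frontal gyrus",
    "superior temporal gyrus",
})

DEFAULT_NON_EXPECTED_REGIONS = frozenset({
    "cerebellum",
    "sub-gyral",
    "insula",
    "postcentral gyrus",
    "supramarginal gyrus",
    "superior frontal gyrus",
})


@dataclasses.dataclass(frozen=True)
class ClusterEntry:
    region_name: str
    voxel_count: int
    max_z: float

    def __post_init__(self) -> None:
        if self.voxel_count <= 0:
            raise ValueError("voxel counts must be positive")


@dataclasses.dataclass
class ClusterReport:
    roi_id: str
    entries: list[ClusterEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"cluster report {self.roi_id} has no entries")

    @property
    def total_voxels(self) -> int:
        return sum(e.voxel_count for e in self.entries)


@dataclasses.dataclass
class RegionPolicy:
    """Region vocabulary and size filter driving the E/NE decision.

    Matching is case-insensitive exact match; the two region sets must be
    disjoint. The defaults seed the language-mapping vocabulary above but
    are fully configurable (the anatomical lists are inherently open-ended).
    """

    expected_regions: frozenset[str] = DEFAULT_EXPECTED_REGIONS
    non_expected_regions: frozenset[str] = DEFAULT_NON_EXPECTED_REGIONS
    min_cluster_voxels: int = 5

    def __post_init__(self) -> None:
        self.expected_regions = frozenset(r.lower() for r in self.expected_regions)
        self.non_expected_regions = frozenset(
            r.lower() for r in self.non_expected_regions)
        if self.expected_regions & self.non_expected_regions:
            raise ValueError("E and NE region sets must be disjoint")

    def classify_region(self, region_name: str) -> str | None:
        name = region_name.lower()
        if name in self.expected_regions:
            return E
        if name in self.non_expected_regions:
            return NE
        return None

    @classmethod
    def from_file(cls, path: str | Path) -> "RegionPolicy":
        text = Path(path).read_text()
        cfg = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
            else json.loads(text)
        return cls(
            expected_regions=frozenset(cfg["expected_regions"]),
            non_expected_regions=frozenset(cfg["non_expected_regions"]),
            min_cluster_voxels=int(cfg.get("min_cluster_voxels", 5)),
        )


def label_cluster(report: ClusterReport, policy: RegionPolicy | None = None) -> str:
    """Assign E or NE to one cluster.

    Entries in regions outside both vocabularies are ignored for the
    decision (but logged). If known entries span both classes, the entry
    with the highest max Z decides; an exact Z tie across classes is
    refused as unlabelable rather than resolved arbitrarily.
    """
    policy = policy or RegionPolicy()
    if report.total_voxels < policy.min_cluster_voxels:
        raise ClusterTooSmallError(
            f"cluster {report.roi_id}: {report.total_voxels} voxels < minimum "
            f"{policy.min_cluster_voxels}")
    known: list[tuple[str, ClusterEntry]] = []
    for entry in report.entries:
        cls = policy.classify_region(entry.region_name)
        if cls is None:
            logger.info("cluster %s: region %r not in vocabulary, ignored",
                        report.roi_id, entry.region_name)
        else:
            known.append((cls, entry))
    if not known:
        raise UnlabelableError(
            f"cluster {report.roi_id}: no region in the E/NE vocabulary; "
            "flag for manual review")
    classes = {cls for cls, _ in known}
    if len(classes) == 1:
        return classes.pop()
    best_z = max(e.max_z for _, e in known)
    winners = {cls for cls, e in known if e.max_z == best_z}
    if len(winners) > 1:
        raise UnlabelableError(
            f"cluster {report.roi_id}: exact Z-score tie across classes; "
            "flag for manual review")
    return winners.pop()


def label_clusters(reports: Iterable[ClusterReport],
                   policy: RegionPolicy | None = None) -> pd.DataFrame:
    """Label a batch of clusters; filtered/unlabelable ones are recorded.

    Returns a frame with roi_id, label (E/NE or NaN) and status
    ('labeled', 'filtered_too_small', 'unlabelable').
    """
    policy = policy or RegionPolicy()
    rows = []
    for rep in reports:
        try:
            rows.append({"roi_id": rep.roi_id,
                         "label": label_cluster(rep, policy),
                         "status": "labeled"})
        except ClusterTooSmallError:
            rows.append({"roi_id": rep.roi_id, "label": None,
                         "status": "filtered_too_small"})
        except UnlabelableError:
            rows.append({"roi_id": rep.roi_id, "label": None,
                         "status": "unlabelable"})
    return pd.DataFrame(rows, columns=["roi_id", "label", "status"])


def summarize_labels(labels: Sequence[str]) -> dict:
    """Class counts and percentage prevalence of a label list."""
    if len(labels) == 0:
        raise ValueError("no labels to summarize")
    n_e = sum(1 for x in labels if x == E)
    n_ne = sum(1 for x in labels if x == NE)
    total = len(labels)
    return {
        "n_total": total,
        "n_e": n_e,
        "n_ne": n_ne,
        "prevalence_e_pct": 100.0 * n_e / total,
        "prevalence_ne_pct": 100.0 * n_ne / total,
    }


def read_cluster_reports(path: str | Path) -> list[ClusterReport]:
    """Cluster reports from CSV with columns roi_id, region, voxels, max_z."""
    df = pd.read_csv(path)
    reports = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        entries = [ClusterEntry(str(r.region), int(r.voxels), float(r.max_z))
                   for r in grp.itertuples()]
        reports.append(ClusterReport(roi_id=str(roi_id), entries=entries))
    return reports
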