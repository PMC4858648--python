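"""Label activation clusters as Expected / Non-Expected from region reports.

Each cluster report lists the anatomical regions an activation cluster
overlaps (with voxel counts and max Z). Clusters wholly inside language
regions are Expected; clusters straddling both vocabularies follow the
higher Z-score; clusters under 5 voxels are filtered out.
"""

from fmritex.labeling import (
    ClusterEntry,
    ClusterReport,
    label_clusters,
    summarize_labels,
)

reports = [
    ClusterReport("broca", [ClusterEntry("inferior frontal gyrus", 42, 6.1)]),
    ClusterReport("mixed", [ClusterEntry("superior temporal gyrus", 11, 5.2),
                            ClusterEntry("insula", 30, 3.1)]),
    ClusterReport("deep_white", [ClusterEntry("sub-gyral", 25, 4.0)]),
    ClusterReport("speck", [ClusterEntry("cerebellum", 4, 3.3)]),
]

labeled = label_clusters(reports)
print(labeled.to_string(index=False))

ok = labeled[labeled["status"] == "labeled"]
print("\nsummary:", summarize_labels(ok["label"].tolist()))
print("\n'mixed' follows the higher-Z entry (E); 'speck' is below the "
      "5-voxel minimum and never reaches the feature table.")
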