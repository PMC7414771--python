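"""Desikan-Killiany cortical parcellation labels and a default lobe partition.

The atlas parcellates each hemisphere into 34 gyral regions (68 cortical
nodes in total).  Labels are ordered left hemisphere first, then right, so
region ``i`` and region ``i + 34`` are homotopic (left-right) counterparts.
"""

from __future__ import annotations

DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

# Coarse lobar assignment used for the default within-module correlation
# structure of synthetic cohorts.  Modules span both hemispheres.
_LOBE_OF: dict[str, str] = {
    "bankssts": "temporal",
    "caudalanteriorcingulate": "cingulate",
    "caudalmiddlefrontal": "frontal",
    "cuneus": "occipital",
    "entorhinal": "temporal",
    "frontalpole": "frontal",
    "fusiform": "temporal",
    "inferiorparietal": "parietal",
    "inferiortemporal": "temporal",
    "insula": "cingulate",
    "isthmuscingulate": "cingulate",
    "lateraloccipital": "occipital",
    "lateralorbitofrontal": "frontal",
    "lingual": "occipital",
    "medialorbitofrontal": "frontal",
    "middletemporal": "temporal",
    "paracentral": "frontal",
    "parahippocampal": "temporal",
    "parsopercularis": "frontal",
    "parsorbitalis": "frontal",
    "parstriangularis": "frontal",
    "pericalcarine": "occipital",
    "postcentral": "parietal",
    "posteriorcingulate": "cingulate",
    "precentral": "frontal",
    "precuneus": "parietal",
    "rostralanteriorcingulate": "cingulate",
    "rostralmiddlefrontal": "frontal",
    "superiorfrontal": "frontal",
    "superiorparietal": "parietal",
    "superiortemporal": "temporal",
    "supramarginal": "parietal",
    "temporalpole": "temporal",
    "transversetemporal": "temporal",
}

_LOBE_IDS: dict[str, int] = {
    "frontal": 0,
    "parietal": 1,
    "temporal": 2,
    "occipital": 3,
    "cingulate": 4,
}


def default_region_labels(n_regions: int = 68) -> list[str]:
    """Left/right paired region labels.

    For ``n_regions == 68`` these are the DK atlas labels ``lh_<name>`` /
    ``rh_<name>``; for any other even count, generic paired labels
    ``lh_region00`` ... are produced so toy problems keep the homotopic
    pairing convention (region ``i`` pairs with ``i + n/2``).
    """
    if n_regions % 2 != 0 or n_regions < 2:
        raise ValueError(f"n_regions must be a positive even integer, got {n_regions}")
    half = n_regions // 2
    if n_regions == 68:
        return [f"lh_{r}" for r in DK_REGIONS] + [f"rh_{r}" for r in DK_REGIONS]
    return [f"lh_region{i:02d}" for i in range(half)] + [
        f"rh_region{i:02d}" for i in range(half)
    ]


def default_module_partition(region_labels: list[str]) -> dict[str, int]:
    """Map each region label to a module id.

    DK labels are grouped into five bilateral lobes; generic labels are cut
    into four contiguous bilateral blocks.
    """
    n = len(region_labels)
    half = n // 2
    stripped = [lab.removeprefix("lh_").removeprefix("rh_") for lab in region_labels]
    if all(s in _LOBE_OF for s in stripped):
        return {
            lab: _LOBE_IDS[_LOBE_OF[s]] for lab, s in zip(region_labels, stripped)
        }
    n_modules = min(4, half)
    return {
        lab: ((i % half) * n_modules) // half for i, lab in enumerate(region_labels)
    }


def homotopic_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Index pairs of left-right counterpart regions under the default order."""
    half = n_regions // 2
    return [(i, i + half) for i in range(half)]
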