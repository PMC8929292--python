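"""Parcellation metadata and the canonical feature-name convention.

Regional features are named ``<modality>:<index>:<region_id>`` where the
modality is one of ``sMRI``, ``fMRI``, ``DTI``, the index is the imaging
metric (GMV/WMV for structural, ALFF/ReHo/DC for functional, FA/MD/AD/RD
for diffusion) and the region id is the 1-based index into the modality's
atlas: the 246-region Brainnetome Atlas (BNA, 210 cortical + 36 subcortical
gray-matter parcels) for sMRI and fMRI, and the 50-region white matter
parcellation map (WMPM) for DTI.

The canonical ordering — modalities in the fixed order sMRI, fMRI, DTI;
indices in the order listed above; regions in ascending atlas order — is an
artifact convention (the source ordering inside a subject's feature vector
is not standardized anywhere); fixing it makes weight vectors comparable
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "AtlasSpec",
    "BNA",
    "WMPM",
    "MODALITIES",
    "MODALITY_INDICES",
    "MODALITY_ATLAS",
    "build_feature_names",
    "parse_feature_name",
    "feature_count",
]


@dataclass(frozen=True)
class AtlasSpec:
    """A parcellation: a name, region count and optional region labels.

    ``n_cortical``/``n_subcortical`` may be given for gray-matter atlases;
    when both are present they must sum to ``n_regions``. Region labels, if
    supplied, carry hemisphere tags (e.g. ``SFG_L_7_1``) and there must be
    exactly one per region.
    """

    name: str
    n_regions: int
    n_cortical: int | None = None
    n_subcortical: int | None = None
    region_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_regions <= 0:
            raise ValueError(f"atlas {self.name!r}: n_regions must be positive")
        if self.n_cortical is not None and self.n_subcortical is not None:
            if self.n_cortical + self.n_subcortical != self.n_regions:
                raise ValueError(
                    f"atlas {self.name!r}: n_cortical + n_subcortical "
                    f"({self.n_cortical} + {self.n_subcortical}) != n_regions "
                    f"({self.n_regions})"
                )
        if self.region_labels and len(self.region_labels) != self.n_regions:
            raise ValueError(
                f"atlas {self.name!r}: {len(self.region_labels)} labels for "
                f"{self.n_regions} regions"
            )

    @property
    def region_ids(self) -> range:
        """1-based atlas indices."""
        return range(1, self.n_regions + 1)


def _default_labels(prefix: str, n: int) -> tuple[str, ...]:
    # Generic hemisphere-tagged placeholders; real atlas label tables can be
    # substituted without changing feature names (names use region ids).
    return tuple(
        f"{prefix}_{(i + 2) // 2}_{'L' if i % 2 else 'R'}" for i in range(1, n + 1)
    )


BNA = AtlasSpec(
    name="BNA",
    n_regions=246,
    n_cortical=210,
    n_subcortical=36,
    region_labels=_default_labels("BNA", 246),
)

WMPM = AtlasSpec(name="WMPM", n_regions=50, region_labels=_default_labels("WMPM", 50))

#: Fixed modality order used everywhere.
MODALITIES: tuple[str, ...] = ("sMRI", "fMRI", "DTI")

#: Imaging indices per modality, in canonical order.
MODALITY_INDICES: dict[str, tuple[str, ...]] = {
    "sMRI": ("GMV", "WMV"),
    "fMRI": ("ALFF", "ReHo", "DC"),
    "DTI": ("FA", "MD", "AD", "RD"),
}

#: Atlas over which each modality's indices are aggregated.
MODALITY_ATLAS: dict[str, AtlasSpec] = {"sMRI": BNA, "fMRI": BNA, "DTI": WMPM}


def _check_modalities(modalities) -> tuple[str, ...]:
    mods = tuple(modalities)
    if not mods:
        raise ValueError("modalities must be a non-empty subset of " + str(MODALITIES))
    unknown = [m for m in mods if m not in MODALITIES]
    if unknown:
        raise ValueError(f"unknown modality name(s): {unknown}; known: {MODALITIES}")
    # canonical order, duplicates collapsed
    return tuple(m for m in MODALITIES if m in mods)


def build_feature_names(
    modalities=MODALITIES,
    atlases: dict[str, AtlasSpec] | None = None,
) -> list[str]:
    """Canonically ordered feature names for a modality subset.

    The full three-modality layout yields 2*246 + 3*246 + 4*50 = 1,430 names.

    Parameters
    ----------
    modalities : iterable of str
        Non-empty subset of ``{"sMRI", "fMRI", "DTI"}``; output order is
        always the canonical one regardless of the order given.
    atlases : dict, optional
        Override the modality -> AtlasSpec mapping (defaults to BNA for
        sMRI/fMRI and WMPM for DTI).
    """
    mods = _check_modalities(modalities)
    atlases = atlases if atlases is not None else MODALITY_ATLAS
    names: list[str] = []
    for mod in mods:
        atlas = atlases[mod]
        for index in MODALITY_INDICES[mod]:
            names.extend(f"{mod}:{index}:{rid}" for rid in atlas.region_ids)
    return names


def feature_count(modalities=MODALITIES) -> int:
    """Number of features in the canonical layout for a modality subset."""
    mods = _check_modalities(modalities)
    return sum(
        len(MODALITY_INDICES[m]) * MODALITY_ATLAS[m].n_regions for m in mods
    )


def parse_feature_name(name: str) -> tuple[str, str, int]:
    """Split ``modality:index:region_id`` and validate the pairing.

    Returns ``(modality, index, region_id)``; raises ``ValueError`` on any
    violation of the naming convention (unknown modality, index not valid
    under that modality, region id out of atlas range).
    """
    parts = name.split(":")
    if len(parts) != 3:
        raise ValueError(f"feature name {name!r} is not 'modality:index:region_id'")
    mod, index, rid_s = parts
    if mod not in MODALITIES:
        raise ValueError(f"feature {name!r}: unknown modality {mod!r}")
    if index not in MODALITY_INDICES[mod]:
        raise ValueError(
            f"feature {name!r}: index {index!r} is not valid under {mod} "
            f"(expected one of {MODALITY_INDICES[mod]})"
        )
    try:
        rid = int(rid_s)
    except ValueError:
        raise ValueError(f"feature {name!r}: region id {rid_s!r} is not an integer")
    atlas = MODALITY_ATLAS[mod]
    if not 1 <= rid <= atlas.n_regions:
        raise ValueError(
            f"feature {name!r}: region id {rid} outside 1..{atlas.n_regions} "
            f"({atlas.name})"
        )
    return mod, index, rid
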