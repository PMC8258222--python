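"""Size-class ladders for stage-structured tree demography.

A scheme is an ordered ladder of size classes (the canonical one runs from
new seedling through DBH classes D10..D80), together with the set of classes
from which a live stem may move *down* a class (retrogression -- realistic
only for the flexible sapling and juvenile stages) and each species' largest
attainable class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: Canonical 12-class ladder: age (<1 yr), height, then 10-cm DBH bins.
CANONICAL_CLASSES: tuple[str, ...] = (
    "new_seedling",
    "aged_seedling",
    "sapling",
    "juvenile",
    "D10",
    "D20",
    "D30",
    "D40",
    "D50",
    "D60",
    "D70",
    "D80",
)


@dataclass(frozen=True)
class SizeClassScheme:
    """Ordered size-class ladder with retrogression rules and species maxima.

    Class indices are 1-based throughout the package so that class ``i``
    matches the conventional subscripts of stage-structured models.

    Parameters
    ----------
    classes
        Ordered, unique class labels; index 1 is the entry class.
    retro_classes
        1-based indices of classes from which retrogression (moving back one
        class) is possible.  Defaults to sapling and juvenile on the
        canonical ladder.
    max_class_by_species
        Map from species label to the largest class index that species can
        attain.  Species absent from the map are assumed able to reach the
        top class.
    """

    classes: tuple[str, ...] = CANONICAL_CLASSES
    retro_classes: frozenset[int] = frozenset({3, 4})
    max_class_by_species: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class labels must be unique")
        if len(self.classes) < 2:
            raise ValueError("a scheme needs at least two classes")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "retro_classes", frozenset(self.retro_classes))
        n = self.n_classes
        bad = [i for i in self.retro_classes if not 2 <= i <= n]
        if bad:
            raise ValueError(
                f"retro_classes {bad} outside the retrogressable range 2..{n}"
            )
        for sp, m in self.max_class_by_species.items():
            if not 1 <= m <= n:
                raise ValueError(f"max class {m} for species {sp!r} not in 1..{n}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index_of(self, label: str) -> int:
        """1-based index of a class label."""
        try:
            return self.classes.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown size class {label!r}") from None

    def label_of(self, index: int) -> str:
        if not 1 <= index <= self.n_classes:
            raise IndexError(f"class index {index} not in 1..{self.n_classes}")
        return self.classes[index - 1]

    def max_class(self, species: str) -> int:
        """Largest attainable class index for ``species`` (ladder top if unknown)."""
        return int(self.max_class_by_species.get(species, self.n_classes))

    def rate_elements(self) -> list[tuple[str, int]]:
        """Enumerate the annual-rate elements the transition model estimates.

        Per species the identifiable elements are stasis S at classes
        2..top (class 1 empties deterministically each year), progression G
        at classes 1..top-1 (the top class cannot advance) and retrogression
        R at the retrogression-capable classes.  On the canonical ladder this
        is the 24-element inventory S(2-12), G(1-11), R(3-4).
        """
        n = self.n_classes
        out: list[tuple[str, int]] = []
        out += [("S", i) for i in range(2, n + 1)]
        out += [("G", i) for i in range(1, n)]
        out += [("R", i) for i in sorted(self.retro_classes)]
        return out

    def n_rate_elements(self, n_species: int = 1) -> int:
        """Number of annual-rate elements for ``n_species`` species."""
        return len(self.rate_elements()) * n_species


#: Species-specific maximum size classes of the 17 focal species of an
#: old-growth temperate forest plot (Ogawa Forest Reserve design), used by
#: the synthetic-data generator.
OGAWA_MAX_CLASS: dict[str, str] = {
    "Betula_grossa": "D80",
    "Carpinus_cordata": "D50",
    "Carpinus_japonica": "D40",
    "Carpinus_tschonoskii": "D50",
    "Carpinus_laxiflora": "D60",
    "Fagus_crenata": "D80",
    "Fagus_japonica": "D80",
    "Quercus_crispula": "D80",
    "Quercus_serrata": "D80",
    "Castanea_crenata": "D80",
    "Cerasus_leveilleana": "D70",
    "Acer_amoenum": "D60",
    "Acer_rufinerve": "D30",
    "Acer_pictum": "D80",
    "Swida_controversa": "D60",
    "Kalopanax_septemlobus": "D80",
    "Styrax_obassia": "D30",
}


def canonical_scheme(species_max: Mapping[str, str] | None = None) -> SizeClassScheme:
    """The canonical 12-class scheme, optionally with species maxima by label."""
    mapping = {}
    if species_max:
        labels = {lab: i + 1 for i, lab in enumerate(CANONICAL_CLASSES)}
        mapping = {sp: labels[lab] for sp, lab in species_max.items()}
    return SizeClassScheme(max_class_by_species=mapping)


def ogawa_scheme() -> SizeClassScheme:
    """Canonical scheme with the 17 focal species' maximum classes."""
    return canonical_scheme(OGAWA_MAX_CLASS)
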