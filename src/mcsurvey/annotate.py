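"""Function categories, localization classes and molecular weights.

Functions of a metacaspase protein are the union of the function categories of
its auxiliary (non-metacaspase) Pfam domains; localization is derived from the
presence of transmembrane helices and the localization annotations of the
domains.  Molecular weight uses standard average residue masses
(``Bio.SeqUtils.molecular_weight``), i.e. the sum of average residue masses
plus one water.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.SeqUtils import molecular_weight as _bio_molecular_weight

from .architecture import METACASPASE_DOMAIN, Architecture
from .errors import ValidationError
from .io_formats import AMINO_ACIDS, DomainAnnotation

LOCALIZATION_CATEGORIES = (
    "Membrane",
    "Extracellular",
    "Intracellular",
    "Membrane and extracellular",
    "Unknown",
)

WATER_MASS = 18.0153

# average residue (amino acid minus water) mass, for the X fallback
_MEAN_RESIDUE_MASS = sum(
    _bio_molecular_weight(aa, seq_type="protein") - WATER_MASS for aa in AMINO_ACIDS
) / len(AMINO_ACIDS)


@dataclass(frozen=True)
class LocalizationCall:
    """The single localization category assigned to one protein."""

    protein_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in LOCALIZATION_CATEGORIES:
            raise ValidationError(f"unknown localization category {self.category!r}")


def _annotation_map(
    annotations: Mapping[str, DomainAnnotation] | Sequence[DomainAnnotation],
) -> Mapping[str, DomainAnnotation]:
    if isinstance(annotations, Mapping):
        return annotations
    return {a.domain_name: a for a in annotations}


def annotate_functions(
    architecture: Architecture,
    annotations: Mapping[str, DomainAnnotation] | Sequence[DomainAnnotation],
    metacaspase_label: str = METACASPASE_DOMAIN,
) -> set[str]:
    """Union of function categories over the auxiliary Pfam domains.

    Domains absent from the annotation table contribute {"unknown"}; a protein
    with no auxiliary domains is {"unknown"}.
    """
    table = _annotation_map(annotations)
    functions: set[str] = set()
    for el in architecture.elements:
        if el.kind != "pfam" or el.label == metacaspase_label:
            continue
        ann = table.get(el.label)
        functions |= set(ann.functions) if ann else {"unknown"}
    return functions or {"unknown"}


def classify_localization(
    architecture: Architecture,
    annotations: Mapping[str, DomainAnnotation] | Sequence[DomainAnnotation],
) -> LocalizationCall:
    """Assign exactly one localization category to a protein.

    Membrane evidence is any transmembrane helix element or membrane-localized
    domain; extracellular / intracellular evidence comes from domain
    annotations.  Membrane + extracellular evidence together yield
    "Membrane and extracellular"; no evidence at all yields "Unknown".
    """
    table = _annotation_map(annotations)
    has_membrane = any(el.kind == "tmh" for el in architecture.elements)
    has_extra = False
    has_intra = False
    for el in architecture.elements:
        if el.kind != "pfam":
            continue
        ann = table.get(el.label)
        if ann is None or ann.localization is None:
            continue
        if ann.localization == "membrane":
            has_membrane = True
        elif ann.localization == "extracellular":
            has_extra = True
        elif ann.localization == "intracellular":
            has_intra = True
    if has_membrane and has_extra:
        category = "Membrane and extracellular"
    elif has_membrane:
        category = "Membrane"
    elif has_extra:
        category = "Extracellular"
    elif has_intra:
        category = "Intracellular"
    else:
        category = "Unknown"
    return LocalizationCall(architecture.protein_id, category)


def molecular_weight(sequence: str, allow_ambiguous: bool = False) -> float:
    """Average molecular mass of a protein chain in Da.

    Sum of average residue masses plus one water; the empty chain weighs one
    water.  The ambiguity code X is rejected unless ``allow_ambiguous`` is
    set, in which case X contributes the mean of the 20 standard residue
    masses.
    """
    bad = set(sequence) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValidationError(f"molecular_weight: invalid residues {sorted(bad)}")
    n_x = sequence.count("X")
    if n_x and not allow_ambiguous:
        raise ValidationError(
            "molecular_weight: ambiguous residue X (set allow_ambiguous to use "
            "an average residue mass)"
        )
    unambiguous = sequence.replace("X", "")
    if not unambiguous:
        base = WATER_MASS
    else:
        base = _bio_molecular_weight(unambiguous, seq_type="protein")
    return base + n_x * _MEAN_RESIDUE_MASS
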