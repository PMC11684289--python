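"""Drug vocabulary: name → (class, molecule, biosimilar flag).

Real dispensing data carry coded product names; here a configurable lookup
table plays that role. A default vocabulary covering the six drug classes used
in IBD care is bundled; users supply their own as YAML for other codings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import yaml

from .config import BIOLOGIC_CLASSES, DRUG_CLASSES


class VocabularyError(KeyError):
    """An unknown drug name, or an inconsistent vocabulary entry."""


@dataclass(frozen=True)
class DrugEntry:
    drug_class: str
    molecule: str
    is_biosimilar: bool = False

    @property
    def is_biologic(self) -> bool:
        return self.drug_class in BIOLOGIC_CLASSES


# name → (class, molecule, biosimilar). Biosimilars map to the originator
# molecule so that a switch between them is recognised as the same compound.
_DEFAULT: Dict[str, Tuple[str, str, bool]] = {
    # conventional: 5-aminosalicylates
    "mesalazine": ("five_asa", "mesalazine", False),
    "sulfasalazine": ("five_asa", "sulfasalazine", False),
    "balsalazide": ("five_asa", "balsalazide", False),
    # conventional: corticosteroids
    "prednisolone": ("corticosteroid", "prednisolone", False),
    "budesonide": ("corticosteroid", "budesonide", False),
    "hydrocortisone": ("corticosteroid", "hydrocortisone", False),
    # conventional: immunomodulators
    "azathioprine": ("immunomodulator", "azathioprine", False),
    "mercaptopurine": ("immunomodulator", "mercaptopurine", False),
    "methotrexate": ("immunomodulator", "methotrexate", False),
    # small molecules
    "tofacitinib": ("small_molecule", "tofacitinib", False),
    # anti-TNF biologics and their biosimilars
    "infliximab": ("anti_tnf", "infliximab", False),
    "infliximab-biosimilar": ("anti_tnf", "infliximab", True),
    "adalimumab": ("anti_tnf", "adalimumab", False),
    "adalimumab-biosimilar": ("anti_tnf", "adalimumab", True),
    "golimumab": ("anti_tnf", "golimumab", False),
    # non-anti-TNF biologics
    "vedolizumab": ("non_anti_tnf", "vedolizumab", False),
    "ustekinumab": ("non_anti_tnf", "ustekinumab", False),
}


class DrugVocabulary:
    """Deterministic drug-name lookup with a strict/lenient switch."""

    def __init__(self, entries: Mapping[str, DrugEntry]):
        for name, entry in entries.items():
            if entry.drug_class not in DRUG_CLASSES:
                raise VocabularyError(
                    f"vocabulary entry {name!r}: unknown drug class "
                    f"{entry.drug_class!r}"
                )
        self._entries = dict(entries)

    @classmethod
    def default(cls) -> "DrugVocabulary":
        return cls(
            {
                name: DrugEntry(cls_, mol, bios)
                for name, (cls_, mol, bios) in _DEFAULT.items()
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "DrugVocabulary":
        """Load ``{drug_name: {drug_class, molecule, is_biosimilar}}`` YAML."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        entries = {}
        for name, spec in raw.items():
            entries[name] = DrugEntry(
                drug_class=spec["drug_class"],
                molecule=spec.get("molecule", name),
                is_biosimilar=bool(spec.get("is_biosimilar", False)),
            )
        return cls(entries)

    def __contains__(self, drug_name: str) -> bool:
        return drug_name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def classify(self, drug_name: str, strict: bool = True) -> DrugEntry:
        """Look up a drug name.

        Unknown names raise :class:`VocabularyError` when ``strict``;
        otherwise they fall into an ``unclassified`` bucket so that the caller
        can report them without silently dropping rows.
        """
        try:
            return self._entries[drug_name]
        except KeyError:
            if strict:
                raise VocabularyError(
                    f"unknown drug name {drug_name!r}; add it to the vocabulary"
                ) from None
            return DrugEntry("unclassified", drug_name, False)


def classify_drug(drug_name: str, vocabulary: DrugVocabulary | None = None,
                  strict: bool = True) -> Tuple[str, str, bool]:
    """Functional wrapper: name → (drug_class, molecule, is_biosimilar)."""
    vocab = vocabulary or DrugVocabulary.default()
    e = vocab.classify(drug_name, strict=strict)
    return e.drug_class, e.molecule, e.is_biosimilar
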