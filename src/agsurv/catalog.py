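"""Three-role drug catalog parameterizing the AG discrimination algorithm.

The algorithm distinguishes three roles a drug product can play:

* ``usual`` — drugs usually prescribed for acute gastroenteritis (AG):
  oral rehydration salts (ORS), oral anti-emetics, probiotic
  antidiarrhoeals, intestinal antipropulsives, intestinal absorbents and
  intestinal anti-infective agents.
* ``possible`` — drugs frequently co-prescribed for AG: antispasmodics.
* ``excluding`` — drugs that signal a non-AG indication when co-dispensed:
  antibiotics, antineoplastics, gastric antacids, drugs for inflammatory
  bowel disease, and injectable anti-emetics.

Each usual or possible product carries ``max_boxes``, the largest number of
boxes still consistent with treating one self-limited AG episode; larger
dispensed volumes point to chronic treatment, home stock or travel packing.
Drugs for peptic ulcer / gastro-oesophageal reflux are deliberately NOT
excluding in this catalog scheme (proton-pump inhibitors are too widely
co-prescribed to carry signal).

Products absent from the catalog are *unlisted*: neutral for every rule,
but they do count toward the rule-D cap on the number of distinct drugs
dispensed.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Union


class TherapeuticClass(str, enum.Enum):
    ORS = "ors"
    ANTIEMETIC_ORAL = "antiemetic_oral"
    PROBIOTIC_ANTIDIARRHOEAL = "probiotic_antidiarrhoeal"
    INTESTINAL_ANTIPROPULSIVE = "intestinal_antipropulsive"
    INTESTINAL_ABSORBENT = "intestinal_absorbent"
    INTESTINAL_ANTIINFECTIVE = "intestinal_antiinfective"
    ANTISPASMODIC = "antispasmodic"
    ANTIBIOTIC = "antibiotic"
    ANTINEOPLASTIC = "antineoplastic"
    GASTRIC_ANTACID = "gastric_antacid"
    IBD_DRUG = "ibd_drug"
    ANTIEMETIC_INJECTABLE = "antiemetic_injectable"


class Role(str, enum.Enum):
    USUAL = "usual"
    POSSIBLE = "possible"
    EXCLUDING = "excluding"


#: Classes a *usual* product may belong to.
USUAL_CLASSES = frozenset(
    {
        TherapeuticClass.ORS,
        TherapeuticClass.ANTIEMETIC_ORAL,
        TherapeuticClass.PROBIOTIC_ANTIDIARRHOEAL,
        TherapeuticClass.INTESTINAL_ANTIPROPULSIVE,
        TherapeuticClass.INTESTINAL_ABSORBENT,
        TherapeuticClass.INTESTINAL_ANTIINFECTIVE,
    }
)

#: The seven "AG therapeutic classes" — the category universe for rules B/C.
AG_CLASSES = USUAL_CLASSES | {TherapeuticClass.ANTISPASMODIC}

EXCLUDING_CLASSES = frozenset(
    {
        TherapeuticClass.ANTIBIOTIC,
        TherapeuticClass.ANTINEOPLASTIC,
        TherapeuticClass.GASTRIC_ANTACID,
        TherapeuticClass.IBD_DRUG,
        TherapeuticClass.ANTIEMETIC_INJECTABLE,
    }
)

#: Classes whose consistent-volume dispense qualifies under rule D.
RULE_D_CLASSES = frozenset(
    {TherapeuticClass.INTESTINAL_ANTIPROPULSIVE, TherapeuticClass.ANTIEMETIC_ORAL}
)

CATALOG_HEADER = ["code", "name", "class", "role", "max_boxes"]


class CatalogError(ValueError):
    """Raised when a catalog file violates the catalog contract."""


@dataclass(frozen=True)
class DrugProduct:
    code: str
    name: str
    therapeutic_class: TherapeuticClass
    role: Role
    max_boxes: Union[int, None] = None

    def __post_init__(self) -> None:
        if self.role in (Role.USUAL, Role.POSSIBLE):
            if self.max_boxes is None:
                raise CatalogError(
                    f"product {self.code!r}: max_boxes is mandatory for "
                    f"{self.role.value} products"
                )
            if self.max_boxes < 1:
                raise CatalogError(f"product {self.code!r}: max_boxes must be >= 1")
        if self.role is Role.USUAL and self.therapeutic_class not in USUAL_CLASSES:
            raise CatalogError(
                f"product {self.code!r}: class {self.therapeutic_class.value} "
                "cannot be role=usual"
            )
        if self.role is Role.POSSIBLE and self.therapeutic_class is not TherapeuticClass.ANTISPASMODIC:
            raise CatalogError(
                f"product {self.code!r}: only antispasmodics may be role=possible"
            )
        if self.role is Role.EXCLUDING and self.therapeutic_class not in EXCLUDING_CLASSES:
            raise CatalogError(
                f"product {self.code!r}: class {self.therapeutic_class.value} "
                "cannot be role=excluding"
            )


class DrugCatalog:
    """Validated mapping of product code -> :class:`DrugProduct`."""

    def __init__(self, products: Iterable[DrugProduct]):
        self._products: Dict[str, DrugProduct] = {}
        for p in products:
            if p.code in self._products:
                raise CatalogError(f"duplicate drug code {p.code!r}")
            self._products[p.code] = p
        if not any(p.role is Role.USUAL for p in self._products.values()):
            raise CatalogError("catalog must contain at least one usual product")

    def __len__(self) -> int:
        return len(self._products)

    def __iter__(self):
        return iter(self._products.values())

    def __contains__(self, code: str) -> bool:
        return code in self._products

    def get(self, code: str) -> Union[DrugProduct, None]:
        return self._products.get(code)

    def role_of(self, code: str) -> str:
        """Role label of ``code``, or ``"unlisted"`` for unknown codes.

        Unlisted drugs neither qualify nor exclude a dispense, but they do
        count toward rule D's distinct-drug cap.
        """
        p = self._products.get(code)
        return p.role.value if p is not None else "unlisted"

    def class_of(self, code: str) -> Union[TherapeuticClass, None]:
        p = self._products.get(code)
        return p.therapeutic_class if p is not None else None

    def max_boxes_of(self, code: str) -> Union[int, None]:
        p = self._products.get(code)
        return p.max_boxes if p is not None else None


def load_catalog(path: Union[str, Path]) -> DrugCatalog:
    """Load and validate a catalog CSV (``code,name,class,role,max_boxes``)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != CATALOG_HEADER:
            raise CatalogError(
                f"{path}: expected header {','.join(CATALOG_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        products = []
        for i, row in enumerate(reader, start=2):
            try:
                cls = TherapeuticClass(row["class"])
            except ValueError:
                raise CatalogError(
                    f"{path}:{i}: unknown therapeutic class {row['class']!r}"
                ) from None
            try:
                role = Role(row["role"])
            except ValueError:
                raise CatalogError(f"{path}:{i}: unknown role {row['role']!r}") from None
            raw_mb = (row.get("max_boxes") or "").strip()
            max_boxes = int(raw_mb) if raw_mb else None
            if role in (Role.USUAL, Role.POSSIBLE) and max_boxes is None:
                raise CatalogError(
                    f"{path}:{i}: product {row['code']!r} is {role.value} but "
                    "max_boxes is missing"
                )
            products.append(
                DrugProduct(
                    code=row["code"],
                    name=row["name"],
                    therapeutic_class=cls,
                    role=role,
                    max_boxes=max_boxes,
                )
            )
    return DrugCatalog(products)


def save_catalog(catalog: DrugCatalog, path: Union[str, Path]) -> None:
    """Write a catalog in the same CSV dialect :func:`load_catalog` reads."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CATALOG_HEADER)
        for p in catalog:
            writer.writerow(
                [
                    p.code,
                    p.name,
                    p.therapeutic_class.value,
                    p.role.value,
                    "" if p.max_boxes is None else p.max_boxes,
                ]
            )


def toy_catalog() -> DrugCatalog:
    """A 12-product toy catalog, one product per therapeutic class.

    Structurally equivalent to a national formulary list but small enough
    to enumerate exhaustively; max_boxes values reflect typical 3-7 day
    AG courses.
    """
    P = DrugProduct
    T = TherapeuticClass
    return DrugCatalog(
        [
            P("U-ORS", "oral rehydration salts", T.ORS, Role.USUAL, 2),
            P("U-AEO", "oral anti-emetic", T.ANTIEMETIC_ORAL, Role.USUAL, 2),
            P("U-PRO", "probiotic antidiarrhoeal", T.PROBIOTIC_ANTIDIARRHOEAL, Role.USUAL, 2),
            P("U-APR", "intestinal antipropulsive", T.INTESTINAL_ANTIPROPULSIVE, Role.USUAL, 2),
            P("U-ABS", "intestinal absorbent", T.INTESTINAL_ABSORBENT, Role.USUAL, 3),
            P("U-AIF", "intestinal anti-infective", T.INTESTINAL_ANTIINFECTIVE, Role.USUAL, 2),
            P("P-ASP", "antispasmodic", T.ANTISPASMODIC, Role.POSSIBLE, 2),
            P("X-ATB", "broad-spectrum antibiotic", T.ANTIBIOTIC, Role.EXCLUDING),
            P("X-ONC", "antineoplastic agent", T.ANTINEOPLASTIC, Role.EXCLUDING),
            P("X-ANT", "gastric antacid", T.GASTRIC_ANTACID, Role.EXCLUDING),
            P("X-IBD", "inflammatory bowel disease drug", T.IBD_DRUG, Role.EXCLUDING),
            P("X-AEI", "injectable anti-emetic", T.ANTIEMETIC_INJECTABLE, Role.EXCLUDING),
        ]
    )
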