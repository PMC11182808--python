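"""Editable code dictionaries: drugs, named regimens, Charlson map, AE codes.

The real-world analysis relies on proprietary regimen and adverse-event code
lists; this package ships configurable CSV stand-ins covering every regimen
and AE category it reports on.  All four dictionaries can be replaced by
user-supplied CSVs with the same headers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

BC_DRUG_CLASSES = frozenset({"anthracycline", "taxane", "ici", "bc_other"})

ANTHRACYCLINE_CONTAINING = "anthracycline_containing"
TAXANE_CONTAINING = "taxane_containing"
OTHER = "other"
CATEGORIES = (ANTHRACYCLINE_CONTAINING, TAXANE_CONTAINING, OTHER)

AE_CATEGORIES = (
    "nausea_vomiting", "neutropenia_leukopenia", "febrile_neutropenia",
    "anemia", "diarrhea", "ild", "peripheral_neuropathy",
)


def _data_path(name: str) -> Path:
    return Path(resources.files("oncolot").joinpath("data", name))  # type: ignore[arg-type]


@dataclass(frozen=True)
class DrugDictionary:
    """Maps opaque drug codes to drug names and class sets.

    Classes: ``anthracycline``, ``taxane``, ``ici``, ``bc_other`` (the four
    breast-cancer treatment classes), ``hormonal``, ``anti_her2``,
    ``ae_treatment:<class>`` for drugs used to treat adverse events, and
    ``non_bc`` for unrelated medication.
    """

    name_by_code: dict[str, str]
    classes_by_code: dict[str, frozenset[str]]

    def __post_init__(self):
        for code, classes in self.classes_by_code.items():
            if not classes:
                raise ValueError(f"drug code {code!r} maps to no class")
            if ("hormonal" in classes or "anti_her2" in classes) and "bc_other" in classes:
                raise ValueError(f"drug code {code!r}: hormonal/anti_her2 cannot co-occur with bc_other")

    def name_of(self, code: str) -> str:
        return self.name_by_code[code]

    def classes_of(self, code: str) -> frozenset[str]:
        return self.classes_by_code[code]

    def code_of(self, name: str) -> str:
        for code, n in self.name_by_code.items():
            if n == name:
                return code
        raise KeyError(name)

    def is_bc_drug(self, code: str) -> bool:
        return bool(self.classes_by_code[code] & BC_DRUG_CLASSES)

    def is_hormonal(self, code: str) -> bool:
        return "hormonal" in self.classes_by_code[code]

    def is_anti_her2(self, code: str) -> bool:
        return "anti_her2" in self.classes_by_code[code]

    def ae_class_of(self, code: str) -> str | None:
        for c in self.classes_by_code[code]:
            if c.startswith("ae_treatment:"):
                return c.split(":", 1)[1]
        return None

    def bc_codes(self) -> set[str]:
        return {c for c in self.classes_by_code if self.is_bc_drug(c)}


@dataclass(frozen=True)
class RegimenDefinition:
    name: str
    components: frozenset[str]  # drug names
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown regimen category {self.category!r}")


@dataclass(frozen=True)
class RegimenCatalog:
    definitions: tuple[RegimenDefinition, ...]

    def by_name(self, name: str) -> RegimenDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise KeyError(name)

    def match(self, components: frozenset[str]) -> RegimenDefinition | None:
        """Longest-matching named definition whose components are covered.

        A definition matches when its component set is a subset of the
        observed set; the match with the most components wins, and is
        returned only if it covers the observed set exactly (otherwise the
        caller falls back to an ad-hoc name).
        """
        best = None
        for d in self.definitions:
            if d.components <= components:
                if best is None or len(d.components) > len(best.components):
                    best = d
        if best is not None and best.components == components:
            return best
        return None


def adhoc_regimen_name(components: frozenset[str]) -> str:
    return "/".join(sorted(c.title() for c in components))


def load_drug_dictionary(path: Path | str | None = None) -> DrugDictionary:
    df = pd.read_csv(path or _data_path("drug_dictionary.csv"))
    return DrugDictionary(
        name_by_code=dict(zip(df["code"], df["name"])),
        classes_by_code={c: frozenset(str(cl).split(";")) for c, cl in zip(df["code"], df["classes"])},
    )


def load_regimen_catalog(path: Path | str | None = None) -> RegimenCatalog:
    df = pd.read_csv(path or _data_path("regimen_catalog.csv"))
    defs = tuple(
        RegimenDefinition(row["name"], frozenset(str(row["components"]).split(";")), row["category"])
        for _, row in df.iterrows()
    )
    return RegimenCatalog(defs)


@dataclass(frozen=True)
class CharlsonMap:
    """Quan-style ICD-10 prefix map with per-category weights and hierarchy."""

    # rows of (category, icd10_prefix, weight, supersedes-or-None)
    rows: tuple[tuple[str, str, int, str | None], ...]

    @property
    def categories(self) -> set[str]:
        return {r[0] for r in self.rows}

    def weight_of(self, category: str) -> int:
        for cat, _, w, _ in self.rows:
            if cat == category:
                return w
        raise KeyError(category)

    def superseded_by(self, category: str) -> str | None:
        for cat, _, _, sup in self.rows:
            if cat == category:
                return sup
        raise KeyError(category)

    def matched_categories(self, icd10_codes) -> set[str]:
        codes = [str(c) for c in icd10_codes]
        out = set()
        for cat, prefix, _, _ in self.rows:
            if cat in out:
                continue
            if any(c.startswith(prefix) for c in codes):
                out.add(cat)
        return out


def load_charlson_map(path: Path | str | None = None) -> CharlsonMap:
    df = pd.read_csv(path or _data_path("charlson_map.csv"), keep_default_na=False)
    rows = []
    for _, r in df.iterrows():
        w = int(r["weight"])
        if w < 0:
            raise ValueError("Charlson weights must be non-negative")
        rows.append((r["category"], r["icd10_prefix"], w, r["supersedes"] or None))
    m = CharlsonMap(tuple(rows))
    for cat in m.categories:
        sup = next(s for c, _, _, s in m.rows if c == cat)
        if sup and sup not in m.categories:
            raise ValueError(f"Charlson category {cat!r} supersedes unknown category {sup!r}")
    return m


@dataclass(frozen=True)
class AECodeMap:
    """ICD-10 prefixes and required AE-treatment drug classes per AE category."""

    prefixes: dict[str, tuple[str, ...]]
    drug_classes: dict[str, tuple[str, ...]]

    def __post_init__(self):
        if set(self.prefixes) != set(AE_CATEGORIES):
            raise ValueError(f"AE categories must be exactly {AE_CATEGORIES}")
        for cat, p in self.prefixes.items():
            if not p:
                raise ValueError(f"AE category {cat!r} has an empty ICD-10 prefix set")


def load_ae_code_map(path: Path | str | None = None) -> AECodeMap:
    df = pd.read_csv(path or _data_path("ae_code_map.csv"))
    return AECodeMap(
        prefixes={r["category"]: tuple(str(r["icd10_prefixes"]).split(";")) for _, r in df.iterrows()},
        drug_classes={r["category"]: tuple(str(r["drug_classes"]).split(";")) for _, r in df.iterrows()},
    )
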