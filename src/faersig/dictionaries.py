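"""Default drug, event and concomitant-category dictionaries.

Substring dictionaries drive every name-based classification in the
pipeline: bowel-cleanser group assignment (brand + generic fragments),
the ischemic-colitis event definition (MedDRA preferred terms under the
gastrointestinal-disorders SOC, code 10017947), and the concomitant
medication categories used in the comorbidity proxy analysis.

All of these are plain data and editable: load/save round-trips through
YAML so a study can swap in its own term lists without touching code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

GROUP_BISACODYL = "bisacodyl"
GROUP_PEG = "PEG"
GROUP_OSS = "OSS"
GROUP_NONE = "none"
DRUG_GROUPS = (GROUP_BISACODYL, GROUP_PEG, GROUP_OSS)

#: recognized but never grouped (tag-only component)
TAG_SODIUM_PHOSPHATE = "sodium_phosphate"


@dataclass
class DrugGroupSpec:
    """One cleanser group: case-insensitive name fragments and the
    component(s) a match implies."""

    name: str
    include_terms: list[str]
    component_tags: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.include_terms:
            raise ConfigError(f"drug group {self.name!r} has no include_terms")
        if not self.component_tags:
            self.component_tags = (self.name,)


@dataclass
class EventSpec:
    """Target adverse event: a flat PT list under one MedDRA SOC."""

    soc_code: str = "10017947"
    pt_terms: list[str] = field(default_factory=lambda: list(DEFAULT_IC_PTS))

    def __post_init__(self):
        if not self.pt_terms:
            raise ConfigError("EventSpec.pt_terms must be non-empty")

    def normalized_terms(self) -> set[str]:
        return {" ".join(t.lower().split()) for t in self.pt_terms}


#: MedDRA preferred terms naming ischemic colitis (spelling variants included)
DEFAULT_IC_PTS = (
    "Colitis ischaemic",
    "Colitis ischemic",
    "Ischaemic colitis",
    "Ischemic colitis",
)


def default_drug_groups() -> list[DrugGroupSpec]:
    """Brand + generic fragments per cleanser group.

    The exact study term lists are configurable; these defaults cover the
    common US/EU brand and generic names for each component.
    """
    return [
        DrugGroupSpec(GROUP_BISACODYL, [
            "bisacodyl", "dulcolax", "correctol", "bisacolax", "fleet laxative",
            "halflytely",
        ]),
        DrugGroupSpec(GROUP_PEG, [
            "polyethylene glycol", "peg 3350", "peg-3350", "peg 4000", "peg-4000",
            "macrogol", "miralax", "golytely", "nulytely", "trilyte", "colyte",
            "glycolax", "moviprep", "plenvu", "gavilyte", "fortrans", "movicol",
            "klean-prep",
        ]),
        DrugGroupSpec(GROUP_OSS, [
            "sodium sulfate", "sodium sulphate", "magnesium sulfate",
            "magnesium sulphate", "potassium sulfate", "oral sulfate", "suprep",
            "sutab", "sodium picosulfate", "sodium picosulphate", "picosulfate",
            "picoprep", "prepopik", "clenpiq", "picolax", "citrafleet", "eziclen",
            "izinova",
        ]),
    ]


def sodium_phosphate_terms() -> list[str]:
    """Sodium-phosphate regimens: recognized and tagged, never grouped."""
    return ["sodium phosphate", "phospho-soda", "osmoprep", "visicol"]


#: Table-8-style concomitant categories, in precedence order; first match wins,
#: "Unknown or Unclassified" is the fallback.
DEFAULT_CONCOMITANT_CATEGORIES: dict[str, list[str]] = {
    "Cardiovascular Drugs": [
        # antihypertensives, antianginals, anticoagulants/antiplatelets,
        # lipid-lowering, antiarrhythmics, vasodilators, heart failure, diuretics
        "amlodipine", "lisinopril", "enalapril", "ramipril", "valsartan",
        "losartan", "candesartan", "metoprolol", "atenolol", "bisoprolol",
        "carvedilol", "diltiazem", "verapamil", "isosorbide", "nitroglycerin",
        "aspirin", "clopidogrel", "warfarin", "apixaban", "rivaroxaban",
        "dabigatran", "heparin", "atorvastatin", "simvastatin", "rosuvastatin",
        "pravastatin", "ezetimibe", "amiodarone", "digoxin", "flecainide",
        "furosemide", "hydrochlorothiazide", "spironolactone", "torsemide",
        "sacubitril", "statin",
    ],
    "Gastrointestinal Drugs": [
        "omeprazole", "pantoprazole", "esomeprazole", "lansoprazole",
        "rabeprazole", "famotidine", "ranitidine", "ondansetron",
        "metoclopramide", "domperidone", "simethicone", "antacid", "sucralfate",
        "mesalamine", "mesalazine", "loperamide",
    ],
    "Antibiotics": [
        "amoxicillin", "ampicillin", "penicillin", "cephalexin", "ceftriaxone",
        "ciprofloxacin", "levofloxacin", "moxifloxacin", "azithromycin",
        "clarithromycin", "doxycycline", "metronidazole", "nitrofurantoin",
        "trimethoprim", "vancomycin",
    ],
    "Analgesics": [
        "acetaminophen", "paracetamol", "ibuprofen", "naproxen", "diclofenac",
        "celecoxib", "tramadol", "oxycodone", "hydrocodone", "morphine",
        "codeine", "fentanyl", "ketorolac",
    ],
    "Antiallergics": [
        "loratadine", "desloratadine", "cetirizine", "levocetirizine",
        "fexofenadine", "diphenhydramine", "chlorpheniramine", "antihistamine",
        "montelukast",
    ],
    "Antidepressants": [
        "sertraline", "fluoxetine", "paroxetine", "citalopram", "escitalopram",
        "venlafaxine", "duloxetine", "bupropion", "mirtazapine", "amitriptyline",
        "nortriptyline", "trazodone",
    ],
    "Hormonal Drugs": [
        "levothyroxine", "liothyronine", "insulin", "metformin", "glimepiride",
        "sitagliptin", "prednisone", "prednisolone", "hydrocortisone",
        "dexamethasone", "estradiol", "estrogen", "progesterone", "testosterone",
        "tamoxifen",
    ],
    "Vitamins and Minerals": [
        "vitamin", "multivitamin", "cholecalciferol", "ergocalciferol",
        "cyanocobalamin", "folic acid", "folate", "thiamine", "calcium",
        "magnesium oxide", "ferrous", "iron", "zinc", "potassium chloride",
    ],
    "Urological Drugs": [
        "tamsulosin", "alfuzosin", "finasteride", "dutasteride", "oxybutynin",
        "solifenacin", "tolterodine", "mirabegron",
    ],
    "Others": [
        "gabapentin", "pregabalin", "levetiracetam", "lamotrigine", "phenytoin",
        "donepezil", "memantine", "zolpidem", "lorazepam", "alprazolam",
        "diazepam", "clonazepam", "albuterol", "salbutamol", "tiotropium",
        "budesonide", "latanoprost", "allopurinol", "levodopa", "quetiapine",
    ],
}

CONCOMITANT_FALLBACK = "Unknown or Unclassified"


@dataclass
class ConcomitantDictionary:
    """Ordered category -> name-fragment lists; fallback is
    ``Unknown or Unclassified``."""

    categories: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CONCOMITANT_CATEGORIES.items()}
    )
    fallback: str = CONCOMITANT_FALLBACK

    def __post_init__(self):
        if self.fallback in self.categories:
            raise ConfigError("fallback category must not carry its own term list")

    def category_names(self) -> list[str]:
        return list(self.categories) + [self.fallback]

    def categorize(self, name: str) -> str:
        low = str(name).lower()
        for cat, fragments in self.categories.items():
            if any(frag in low for frag in fragments):
                return cat
        return self.fallback


# ---------------------------------------------------------------------------
# YAML round-trip so dictionaries ship as editable config files


def save_dictionaries(path: str | Path,
                      drug_groups: list[DrugGroupSpec] | None = None,
                      event: EventSpec | None = None,
                      concomitant: ConcomitantDictionary | None = None) -> None:
    drug_groups = drug_groups if drug_groups is not None else default_drug_groups()
    event = event if event is not None else EventSpec()
    concomitant = concomitant if concomitant is not None else ConcomitantDictionary()
    payload = {
        "drug_groups": [
            {"name": g.name, "include_terms": g.include_terms,
             "component_tags": list(g.component_tags)} for g in drug_groups
        ],
        "event": {"soc_code": event.soc_code, "pt_terms": event.pt_terms},
        "concomitant_categories": concomitant.categories,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


def load_dictionaries(path: str | Path) -> tuple[list[DrugGroupSpec], EventSpec, ConcomitantDictionary]:
    try:
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        groups = [DrugGroupSpec(g["name"], list(g["include_terms"]),
                                tuple(g.get("component_tags", ())))
                  for g in payload["drug_groups"]]
        event = EventSpec(str(payload["event"]["soc_code"]),
                          list(payload["event"]["pt_terms"]))
        conc = ConcomitantDictionary({k: list(v) for k, v in
                                      payload["concomitant_categories"].items()})
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ConfigError(f"bad dictionary file {path}: {exc}") from exc
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ConfigError("drug group names must be unique")
    return groups, event, conc
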