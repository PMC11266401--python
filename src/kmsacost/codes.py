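"""Diagnosis/procedure code vocabularies and case-identification criteria.

Claims carry diagnosis codes as a compact string ``"sys:code;sys:code;..."``
with ``sys`` in ``{icd9, icd10}`` and position 1 primary. The AL-amyloidosis
case rule and the comorbidity categories are configurable code sets; the
comorbidity lists shipped here are illustrative clinical defaults (heart
failure / cardiomyopathy, chronic kidney disease and nephrotic syndrome,
chronic liver disease, chronic pulmonary disease, polyneuropathy, and
malignancy) — users with validated lists should substitute their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

COMORBIDITY_CATEGORIES = (
    "cardiac",
    "liver",
    "renal",
    "pulmonary",
    "neuropathy",
    "malignancy",
)

#: illustrative default ICD code prefixes per comorbidity category
DEFAULT_CODELISTS: dict[str, dict[str, tuple[str, ...]]] = {
    "cardiac": {"icd10": ("I50", "I42", "I31"), "icd9": ("428", "425")},
    "liver": {"icd10": ("K72", "K74", "K76"), "icd9": ("571", "573")},
    "renal": {"icd10": ("N18", "N04", "N08"), "icd9": ("585", "581")},
    "pulmonary": {"icd10": ("J44", "J47", "J84"), "icd9": ("496", "515")},
    "neuropathy": {"icd10": ("G62", "G63", "G90"), "icd9": ("356", "357")},
    "malignancy": {"icd10": ("C90", "C34", "C50", "C18"), "icd9": ("203", "162")},
}

#: generic filler diagnoses for non-informative claims; none shares a prefix
#: with the AL, switch, registry or default comorbidity code sets
GENERIC_DX = ("J06.9", "I10", "E11.9", "M54.5", "K29.7", "L30.9", "H52.1")

DEFAULT_BIOPSY_CODES = ("BX001", "BX002")


@dataclass(frozen=True)
class CodeList:
    """One comorbidity category with prefix-matched ICD-9/ICD-10 code sets."""

    category: str
    icd9_codes: tuple[str, ...]
    icd10_codes: tuple[str, ...]

    def __post_init__(self):
        if self.category not in COMORBIDITY_CATEGORIES:
            raise ValueError(f"unknown comorbidity category: {self.category!r}")
        if not (self.icd9_codes or self.icd10_codes):
            raise ValueError(f"empty code list for {self.category!r}")


def default_codelists() -> tuple[CodeList, ...]:
    return tuple(
        CodeList(cat, tuple(v["icd9"]), tuple(v["icd10"]))
        for cat, v in DEFAULT_CODELISTS.items()
    )


def load_codelists(path) -> tuple[CodeList, ...]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(
        CodeList(cat, tuple(v.get("icd9", ())), tuple(v.get("icd10", ())))
        for cat, v in raw.items()
    )


@dataclass(frozen=True)
class CaseCriteria:
    """Claims-based rule identifying newly diagnosed AL amyloidosis.

    A patient qualifies with >= 1 inpatient claim, or >= 2 outpatient claims
    at least ``outpatient_gap_days`` apart, bearing a qualifying code in any
    diagnosis position, plus a biopsy procedure claim inside
    ``biopsy_window_days`` around the index date (the first qualifying-code
    claim of any setting). Exclusions: any 2015 claim with the legacy ICD-9
    amyloidosis code, a later switch to a non-AL amyloidosis code, or a
    confirmed non-AL registry flag.
    """

    qualifying_codes: frozenset[str] = frozenset({"E85.4", "E85.8", "E85.9"})
    min_inpatient: int = 1
    min_outpatient: int = 2
    outpatient_gap_days: int = 30
    biopsy_window_days: tuple[int, int] = (-365, 182)
    biopsy_codes: frozenset[str] = frozenset(DEFAULT_BIOPSY_CODES)
    exclusion_codes_2015: frozenset[str] = frozenset({"277.3"})  # icd9
    # "E83.3" implemented as printed in the source criteria; if it is a typo
    # for E85.3 (familial amyloidosis) substitute via `replace`.
    switch_codes: frozenset[str] = frozenset({"E85.0", "E85.1", "E85.2", "E83.3"})
    registry_nonal_codes: frozenset[tuple[str, str]] = frozenset(
        {("icd9", "277.3"), ("icd10", "E85.1")}
    )

    def with_(self, **kw) -> "CaseCriteria":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# dx string helpers

def encode_dx(codes: list[tuple[str, str]]) -> str:
    """Encode an ordered [(system, code), ...] list as ``sys:code;...``."""
    return ";".join(f"{s}:{c}" for s, c in codes)


def explode_dx(claims: pd.DataFrame) -> pd.DataFrame:
    """Long table of diagnosis codes: one row per (claim row, dx position).

    Returns columns ``claim_idx, position, system, code`` where ``claim_idx``
    indexes into ``claims``'s positional order.
    """
    dx = claims["dx"].fillna("")
    parts = dx.str.split(";")
    lengths = parts.str.len().where(dx != "", 0)
    claim_idx = claims.index.repeat(lengths)
    flat = [p for row in parts[dx != ""] for p in row]
    if not flat:
        return pd.DataFrame(columns=["claim_idx", "position", "system", "code"])
    sys_code = pd.Series(flat).str.split(":", n=1, expand=True)
    pos = [i + 1 for row in parts[dx != ""] for i in range(len(row))]
    return pd.DataFrame(
        {
            "claim_idx": claim_idx.to_numpy(),
            "position": pos,
            "system": sys_code[0].to_numpy(),
            "code": sys_code[1].to_numpy(),
        }
    )


def match_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    """Boolean mask: code starts with any of the prefixes."""
    if not prefixes:
        return pd.Series(False, index=codes.index)
    mask = codes.str.startswith(prefixes[0])
    for p in prefixes[1:]:
        mask |= codes.str.startswith(p)
    return mask
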