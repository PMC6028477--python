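"""Salt-to-ion stoichiometry for modified LS macronutrient media.

The rooting experiment varies four macronutrient salts — KNO3, NH4NO3,
Ca(NO3)2·4H2O and CaCl2·2H2O — across 36 factorial formulations, and models
the five resulting ion concentrations (NO3-, NH4+, K+, Ca2+, Cl-, all mM).
This module converts salt masses (mg/L) into the ion profile that the
surrogate models take as input, and cross-checks recomputed profiles against
a reference ion table.

Two chloride conventions are exposed.  The published ion table reports Cl-
equal to the molarity of CaCl2·2H2O (one Cl- per formula unit); strict
stoichiometry gives two.  ``per_salt`` (the default) reproduces the published
table; ``stoichiometric`` applies the factor of two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MediumFormulation",
    "MolarMassTable",
    "IonProfile",
    "ION_ORDER",
    "ions_from_salts",
    "load_formulations",
    "load_reference_table",
    "verify_against_reference",
]

#: Canonical ion ordering used throughout the package (model input order).
ION_ORDER: tuple[str, ...] = ("no3", "nh4", "k", "ca", "cl")

SALT_NAMES: tuple[str, ...] = ("kno3", "nh4no3", "ca_no3_2_4h2o", "cacl2_2h2o")

ClConvention = Literal["per_salt", "stoichiometric"]


@dataclass(frozen=True)
class MediumFormulation:
    """One macronutrient recipe: salt masses in mg/L."""

    code: int
    kno3: float
    nh4no3: float
    ca_no3_2_4h2o: float
    cacl2_2h2o: float

    def __post_init__(self) -> None:
        for name in SALT_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"medium {self.code}: {name} mass must be finite and >= 0, got {value}"
                )


@dataclass(frozen=True)
class MolarMassTable:
    """Molar masses (g/mol) of the four macronutrient salts.

    Defaults use the tetrahydrate of calcium nitrate and the dihydrate of
    calcium chloride — the hydrate identities consistent with the published
    Ca2+ values (2.35, 1.18, 3.00, 1.50 mM).
    """

    kno3: float = 101.10
    nh4no3: float = 80.04
    ca_no3_2_4h2o: float = 236.15
    cacl2_2h2o: float = 147.02

    def __post_init__(self) -> None:
        for name in SALT_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"molar mass {name} must be finite and > 0, got {value}")


@dataclass(frozen=True)
class IonProfile:
    """Five-ion input vector in mM, ordered as :data:`ION_ORDER`."""

    no3: float
    nh4: float
    k: float
    ca: float
    cl: float

    def __post_init__(self) -> None:
        for name in ION_ORDER:
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"ion {name} must be finite and >= 0, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in ION_ORDER], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "IonProfile":
        if len(values) != 5:
            raise ValueError(f"expected 5 ion values, got {len(values)}")
        return cls(**dict(zip(ION_ORDER, map(float, values))))

    def round(self, ndigits: int = 2) -> "IonProfile":
        """Display rounding (the reference table prints 2 decimals)."""
        return IonProfile(**{n: round(getattr(self, n), ndigits) for n in ION_ORDER})


def ions_from_salts(
    formulation: MediumFormulation,
    masses: MolarMassTable | None = None,
    cl_convention: ClConvention = "per_salt",
) -> IonProfile:
    """Convert a salt formulation (mg/L) into ionic concentrations (mM).

    mg/L divided by g/mol is mmol/L.  K+ comes from KNO3 alone, NH4+ from
    NH4NO3 alone, NO3- accumulates from all three nitrate salts (two per
    calcium nitrate), Ca2+ from either calcium salt, and Cl- from CaCl2·2H2O
    under the chosen convention.
    """
    if masses is None:
        masses = MolarMassTable()
    if cl_convention not in ("per_salt", "stoichiometric"):
        raise ValueError(f"unknown cl_convention {cl_convention!r}")

    k = formulation.kno3 / masses.kno3
    nh4 = formulation.nh4no3 / masses.nh4no3
    ca_from_nitrate = formulation.ca_no3_2_4h2o / masses.ca_no3_2_4h2o
    ca_from_chloride = formulation.cacl2_2h2o / masses.cacl2_2h2o
    no3 = k + nh4 + 2.0 * ca_from_nitrate
    ca = ca_from_nitrate + ca_from_chloride
    cl = ca_from_chloride if cl_convention == "per_salt" else 2.0 * ca_from_chloride
    return IonProfile(no3=no3, nh4=nh4, k=k, ca=ca, cl=cl)


_FORMULATION_COLUMNS = {
    "code": "code",
    "kno3_mg_l": "kno3",
    "nh4no3_mg_l": "nh4no3",
    "cano3_2_4h2o_mg_l": "ca_no3_2_4h2o",
    "cacl2_2h2o_mg_l": "cacl2_2h2o",
}


def packaged_fixture(name: str) -> Path:
    """Path to a CSV shipped with the package (``table9_salts`` or
    ``table6_ions_responses``)."""
    ref = resources.files("rootmedia.data").joinpath(f"{name}.csv")
    return Path(str(ref))


def load_formulations(source: str | Path | None = None) -> list[MediumFormulation]:
    """Load salt formulations from CSV; defaults to the packaged 36-recipe table.

    The CSV must carry the columns ``code, kno3_mg_l, nh4no3_mg_l,
    cano3_2_4h2o_mg_l, cacl2_2h2o_mg_l``.  Order is preserved; duplicate codes
    and non-numeric masses are rejected with the offending row index.
    """
    if source is None:
        source = packaged_fixture("table9_salts")
    df = pd.read_csv(source)
    missing = set(_FORMULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")

    out: list[MediumFormulation] = []
    seen: set[int] = set()
    for idx, row in df.iterrows():
        try:
            kwargs = {attr: float(row[col]) for col, attr in _FORMULATION_COLUMNS.items()}
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: non-numeric value ({exc})") from None
        if not float(kwargs["code"]).is_integer():
            raise ValueError(f"row {idx}: code must be an integer")
        kwargs["code"] = int(kwargs["code"])
        if kwargs["code"] in seen:
            raise ValueError(f"row {idx}: duplicate code {kwargs['code']}")
        seen.add(kwargs["code"])
        try:
            out.append(MediumFormulation(**kwargs))
        except ValueError as exc:
            raise ValueError(f"row {idx}: {exc}") from None
    return out


def load_reference_table(source: str | Path | None = None) -> pd.DataFrame:
    """Load the reference treatment table (ion mM + response means/SEs).

    Defaults to the packaged 36-treatment table; returns it indexed by code.
    """
    if source is None:
        source = packaged_fixture("table6_ions_responses")
    df = pd.read_csv(source)
    required = {"code"} | {f"{ion}_mm" for ion in ION_ORDER}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    return df.set_index("code", drop=False)


def reference_ion_profiles(source: str | Path | None = None) -> list[IonProfile]:
    """Ion profiles of the reference table, in row order."""
    df = load_reference_table(source)
    return [
        IonProfile(**{ion: float(row[f"{ion}_mm"]) for ion in ION_ORDER})
        for _, row in df.iterrows()
    ]


@dataclass
class DiscrepancyReport:
    """Per-medium, per-ion absolute differences against a reference."""

    codes: list[int]
    differences: pd.DataFrame  # index code, columns ION_ORDER
    tol: float
    flags: pd.DataFrame = field(init=False)  # boolean, same shape

    def __post_init__(self) -> None:
        self.flags = self.differences > self.tol

    @property
    def n_flagged(self) -> int:
        return int(self.flags.to_numpy().sum())

    def flagged_entries(self) -> list[tuple[int, str, float]]:
        out = []
        for code in self.differences.index:
            for ion in ION_ORDER:
                if self.flags.at[code, ion]:
                    out.append((int(code), ion, float(self.differences.at[code, ion])))
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "tol_mM": self.tol,
            "n_flagged": self.n_flagged,
            "flagged": [
                {"code": c, "ion": i, "abs_diff_mM": d} for c, i, d in self.flagged_entries()
            ],
            "max_abs_diff_mM": float(self.differences.to_numpy().max(initial=0.0)),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def verify_against_reference(
    formulations: Iterable[MediumFormulation],
    reference_ions: Sequence[IonProfile],
    tol: float = 0.02,
    masses: MolarMassTable | None = None,
    cl_convention: ClConvention = "per_salt",
    codes: Sequence[int] | None = None,
) -> DiscrepancyReport:
    """Recompute ions from salts and compare against reference profiles.

    ``codes`` gives the reference codes (defaults to formulation codes, which
    must then match positionally).  Differences above ``tol`` (mM, on
    unrounded values) are flagged.
    """
    formulations = list(formulations)
    if len(formulations) != len(reference_ions):
        raise ValueError(
            f"length mismatch: {len(formulations)} formulations vs "
            f"{len(reference_ions)} reference profiles"
        )
    form_codes = [f.code for f in formulations]
    if codes is not None and list(codes) != form_codes:
        raise ValueError("formulation codes do not match reference codes")

    computed = np.array(
        [ions_from_salts(f, masses, cl_convention).as_array() for f in formulations]
    )
    reference = np.array([p.as_array() for p in reference_ions])
    diffs = pd.DataFrame(
        np.abs(computed - reference), index=pd.Index(form_codes, name="code"), columns=ION_ORDER
    )
    return DiscrepancyReport(codes=form_codes, differences=diffs, tol=tol)


def ion_table(
    formulations: Iterable[MediumFormulation],
    masses: MolarMassTable | None = None,
    cl_convention: ClConvention = "per_salt",
) -> pd.DataFrame:
    """Tabulate ion profiles for a set of formulations (columns ``*_mm``)."""
    rows = []
    for f in formulations:
        profile = ions_from_salts(f, masses, cl_convention)
        rows.append({"code": f.code, **{f"{i}_mm": getattr(profile, i) for i in ION_ORDER}})
    return pd.DataFrame(rows)
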