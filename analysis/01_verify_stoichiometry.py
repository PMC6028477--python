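"""Check that the 36 salt formulations reproduce the published ion table.

Converts each medium's salt masses (mg/L of KNO3, NH4NO3, Ca(NO3)2·4H2O,
CaCl2·2H2O) to ion molarities and compares them with the reference ion
columns under both chloride conventions.  Finding: under the per-salt
convention every ion of every medium agrees within 0.01 mM; under strict
stoichiometry (two Cl- per CaCl2) the chloride column of media 19-36 is
exactly a factor of two off, confirming the reference table counts one Cl-
per formula unit.
"""

from pathlib import Path

from rootmedia.media import (
    ion_table,
    load_formulations,
    reference_ion_profiles,
    verify_against_reference,
)

OUT = Path("results")
OUT.mkdir(exist_ok=True)

formulations = load_formulations()
reference = reference_ion_profiles()

ion_table(formulations).to_csv(OUT / "ion_profiles.csv", index=False)

for convention in ("per_salt", "stoichiometric"):
    report = verify_against_reference(
        formulations, reference, tol=0.02, cl_convention=convention
    )
    report.to_json(OUT / f"stoichiometry_{convention}.json")
    print(
        f"{convention:14s}: {report.n_flagged:2d} entries beyond 0.02 mM "
        f"(max |diff| {report.differences.to_numpy().max():.4f} mM)"
    )
    if report.n_flagged:
        codes = sorted({c for c, _, _ in report.flagged_entries()})
        ions = sorted({i for _, i, _ in report.flagged_entries()})
        print(f"                flagged media {codes[0]}–{codes[-1]}, ions {ions}")
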