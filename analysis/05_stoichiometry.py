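"""Solution-chemistry numbers behind the aggregation interpretation.

Computes the albumin molarity at the working concentration, the pH of the
acid-stabilized magnetite colloid, and the protein-molecules-per-
nanoparticle ratio across the magnetite titration.  Writes a CSV table to
results/.
"""

import csv
from pathlib import Path

import numpy as np

from albumag.pipeline import (
    StoichiometryInput,
    molecules_per_nanoparticle,
    ph_from_hplus,
    protein_molarity,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    molarity = protein_molarity(50.0, 66_500.0)
    print(f"albumin at 50 mg/mL (66.5 kDa): {molarity:.3f} mmol/L")
    print(f"pH of 1e-5 mol/L H+ colloid:    {ph_from_hplus(1e-5):.1f}")

    rows = []
    for n_mf in np.logspace(-5, 0, 11):
        ratio = molecules_per_nanoparticle(StoichiometryInput(mf_concentration=n_mf))
        rows.append((n_mf, ratio))
    out = RESULTS / "stoichiometry.csv"
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n_mf_mg_L", "protein_molecules_per_nanoparticle"])
        for n_mf, ratio in rows:
            writer.writerow([f"{n_mf:.6e}", f"{ratio:.6e}"])
    print("\nn_MF [mg/L]    molecules per nanoparticle")
    for n_mf, ratio in rows:
        marker = "  <- in the 1e8-1e10 window" if 1e8 <= ratio <= 1e10 else ""
        print(f"{n_mf:11.3e}    {ratio:11.3e}{marker}")
    print(f"\ntable: {out}")


if __name__ == "__main__":
    main()
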