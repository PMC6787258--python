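#!/usr/bin/env python
"""Tube-coverage estimate from elastic theory.

Combines the membrane bending rigidity (k_c ~ 20 k_BT for fluid bilayers)
with the curvature-dependent binding free energy — taken from the
curvature-sensing driver's output when available, otherwise the -2 k_BT at
25 nm reference value — into the areal protein density required to
stabilize a tube of that radius.
"""

import json
from pathlib import Path

from bucklesense import required_density

RESULTS = Path(__file__).resolve().parent.parent / "results"
OUT = RESULTS / "tube_coverage"

KC = 20.0  # k_BT
R_BIND = 25.0  # nm
DG_FALLBACK = -2.0  # k_BT


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sensing_summary = RESULTS / "curvature_sensing" / "summary.json"
    if sensing_summary.exists():
        dG = json.loads(sensing_summary.read_text())["dG_bind_kBT"]
        source = "recovered by 02_curvature_sensing.py"
    else:
        dG = DG_FALLBACK
        source = "reference value (run 02_curvature_sensing.py first to measure it)"

    cov = required_density(KC, R_BIND, dG)
    payload = {"dG_source": source, **cov.as_dict()}
    (OUT / "coverage.json").write_text(json.dumps(payload, indent=2) + "\n")

    print(f"dG_bind = {dG:.3f} k_BT at R = {R_BIND:.0f} nm ({source})")
    print(f"bending cost f_tube = {cov.f_tube:.4f} k_BT/nm^2")
    print(f"required density rho = {cov.rho:.4f} nm^-2 "
          f"-> one protein per {cov.area_per_protein:.0f} nm^2")
    print(f"table -> {OUT / 'coverage.json'}")


if __name__ == "__main__":
    main()
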