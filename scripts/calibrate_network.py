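"""Calibration helper for the Waste Incinerator parameter presets.

The shipped presets (src/copulacd/presets/waste_{medium,high}.json) were
chosen with this script so that the analytic continuous-part correlation
matrix meets the two regimes' conditioning targets:

  medium : condition number < 30  (well-conditioned)
  high   : condition number > 1000 (close to singular)

Run it after editing a preset to re-check the targets:

    python scripts/calibrate_network.py
"""

import numpy as np

from copulacd.simulate import waste_incinerator


def report(regime: str) -> None:
    net = waste_incinerator(regime)
    corr = net.analytic_correlation()
    cont = [v for v in net.nodes if v in net.continuous]
    w = np.linalg.eigvalsh(corr.loc[cont, cont].to_numpy())
    print(f"{regime:7s} condition number = {w[-1] / w[0]:10.1f}   "
          f"min eigenvalue = {w[0]:.5f}")


if __name__ == "__main__":
    for regime in ("medium", "high"):
        report(regime)
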