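#!/usr/bin/env python
"""Carbon stocks and annual net emissions per scenario, 2012-2025.

Applies the committed-emission bookkeeping (forest carbon 0.485 of dry
biomass released in the clearing year; secondary vegetation accumulating
carbon linearly with age at 0.45 of its growing biomass) to each
scenario's trajectory, writes the closed ledger, and reports the
cross-scenario ordering of cumulative net emissions.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from lucsim.carbon import forest_carbon, ledger_from_run, summarize
from lucsim.pipeline import RunConfig, build_scenario, simulate_scenario, synthesize_history

SEED = 20120801
OUT = Path(__file__).resolve().parents[1] / "results" / "carbon"


def main() -> None:
    warnings.simplefilter("ignore")
    cfg = RunConfig(seed=SEED, n_rows=200, n_cols=200, years=13)
    hist = synthesize_history(cfg)
    fc = forest_carbon(hist["land"].biomass, cfg.carbon).values
    OUT.mkdir(parents=True, exist_ok=True)

    ledgers, summaries = [], {}
    for name in cfg.scenario_names:
        built = build_scenario(name, hist, cfg)
        run = simulate_scenario(built, hist, cfg)
        ledger = ledger_from_run(run["snapshots"], fc, hist["lc2012"].cell_area_ha,
                                 cfg.start_year, name, cfg.carbon,
                                 regions=built["regions"].values)
        ledgers.append(ledger)
        summaries[name] = summarize(ledger, run["areas"]["FOREST"])[name]

    pd.concat(ledgers, ignore_index=True).to_csv(OUT / "carbon_ledger.csv", index=False)
    summary = pd.DataFrame(summaries).T
    summary.to_csv(OUT / "summary.csv")

    print("carbon ledger written to", OUT)
    print("\nper-scenario summary:")
    print(summary.round(2).to_string())
    nets = {k: v["cumulative_net_MgC"] for k, v in summaries.items()}
    ordered = nets["BASELINE"] >= nets["CODE2012"] >= nets["CODE1965"]
    print("\ncumulative net emissions ordering "
          f"baseline >= 2012-rules >= 1965-rules: {ordered}")
    print("(wide riparian protection shifts clearing from high-carbon forest "
          "to low-carbon secondary vegetation, so full 1965-code compliance "
          "emits least)")


if __name__ == "__main__":
    main()
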