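"""End-to-end pipeline on generated CSV inputs.

Writes synthetic balance logs and a specimen table to a temporary
directory, runs the full pipeline (drying fits -> per-species summaries),
and prints the per-leaf results from the JSON report.  The same flow is
available from the shell:

    cuticle simulate --kind drying --seed 0 --out leaf1.csv
    cuticle all --specimens specimens.csv --log L1 leaf1.csv --out-dir out/
"""

import tempfile
from pathlib import Path

import pandas as pd

import cuticle as c
from cuticle.io import run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    logs = {}
    rows = []
    for i in range(3):
        sp, obs, truth = c.simulate_drying(
            c.DryingSimConfig(seed=i, balance_noise_sd=5e-4)
        )
        path = tmp / f"leaf{i}.csv"
        pd.DataFrame(
            [{"time_s": o.time, "fresh_weight_g": o.fresh_weight,
              "leaf_temp_C": o.leaf_temp, "air_temp_C": o.air_temp}
             for o in obs]
        ).to_csv(path, index=False)
        logs[f"L{i}"] = path
        rows.append(
            f"L{i},{sp.species},{sp.saturated_weight},{sp.dry_weight},"
            f"{sp.projected_area_total}"
        )
    spec_csv = tmp / "specimens.csv"
    spec_csv.write_text(
        "leaf_id,species,saturated_weight_g,dry_weight_g,"
        "projected_area_total_m2\n" + "\n".join(rows) + "\n"
    )

    report = run_pipeline(spec_csv, logs, tmp / "out")
    print(f"{'leaf':<6}{'g_min (m/s)':<14}{'RWD_SC':<8}LMA (g/m^2)")
    for row in report["gmin_per_leaf"]:
        print(f"{row['leaf_id']:<6}{row['g_min_m_per_s']:<14.3e}"
              f"{row['rwd_sc']:<8.3f}{row['lma_g_m2']:.1f}")
    print(f"\nfull report: {tmp / 'out' / 'report.json'} "
          "(deterministic: identical bytes on rerun)")

# All three leaves were generated with true g_min = 6.9e-5 m/s and
# RWD_SC = 0.14; the fitted values show the scatter a 0.5 mg balance adds.
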