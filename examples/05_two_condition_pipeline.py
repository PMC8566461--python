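"""End-to-end two-condition experiment from a single config.

Runs the built-in demo: epithelial-like (peripheral cargo, mixing weight
0.2) vs mesenchymal-like (perinuclear cargo, weight 0.8) scenes, per-cell
compartment maxima, and an unpaired two-tailed t-test per metric — the
pipeline analog of comparing trafficking states across cell lines. The run
writes tidy CSVs plus a manifest from which every table is re-derivable.
"""

import tempfile

import traffiq as tq

with tempfile.TemporaryDirectory() as outdir:
    result = tq.run({
        "outdir": outdir,
        "seed": 1,
        "analyses": ["demo"],
        "simulate": {"n_cells": 30},
        "params": {"demo": {"n_cells": 30}},
    })
    demo = result["tables"]["demo_comparison"].copy()
    demo[["mean", "sem"]] = demo[["mean", "sem"]].round(1)
    demo["p_value"] = demo["p_value"].map("{:.2e}".format)
    print(demo[["metric", "group", "n", "mean", "sem", "p_value"]]
          .to_string(index=False))
    print("\n-> perinuclear maxima are higher in mesenchymal-like cells and")
    print("   peripheral maxima higher in epithelial-like cells; both contrasts")
    print("   separate at p << 0.01 with 30 cells per condition.")
    print(f"\nwritten tables: {sorted(result['outputs'])}")
    print("manifest.json records parameters, versions and hashes; re-running")
    print("from it (traffiq.run_from_manifest) reproduces every CSV byte-for-byte.")
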