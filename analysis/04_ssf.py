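"""Fit the site-scale step selection functions.

Builds 1:10 matched strata from the per-category empirical step
distributions, fits (a) the road-use indicator SSFs and (b) the
distance-to-infrastructure SSFs for all steps and each time-of-day x
behavior subset, and runs the leave-one-territory-out Wilcoxon rank
validation of the distance models. Writes results/ssf_fits.json.
"""

import argparse
import importlib.util
import json
import sys
import warnings
from pathlib import Path

import numpy as np

_spec = importlib.util.spec_from_file_location(
    "analysis_cluster", Path(__file__).with_name("02_cluster_steps.py")
)
_clmod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_clmod)


def main(argv=None):
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args(argv)

    from wolfroads.pipeline import ssf_stage

    warnings.filterwarnings("ignore")
    cfg, study, _meta, clustered, seeds = _clmod.prepare(args.seed)
    res = ssf_stage(study, clustered, cfg, seeds[1])

    ru = res["road_use"]["all"]
    n_real = ru.meta["n_real_on_gravel"]
    n_strata = ru.meta["n_strata"]
    print(f"{n_strata} strata; {n_real} real steps on gravel "
          f"({100*n_real/n_strata:.1f}%), {ru.meta['n_real_on_main']} on main")
    print(f"all steps: gravel beta={ru.params['on_gravel']:.3f} "
          f"(odds ratio {np.exp(ru.params['on_gravel']):.1f}), "
          f"main beta={ru.params['on_main']:.3f}")
    for key, fit in res["road_use"].items():
        if key == "all" or fit is None:
            continue
        g = fit.params.get("on_gravel", float("nan"))
        print(f"  {key:<13} gravel beta={g:+.3f}  "
              f"{'UNSTABLE' if fit.flags.get('unstable') else ''}")
    print("distance-model cross-validation (one-sided Wilcoxon):")
    for key, cv in res["crossvalidation"].items():
        if cv is None:
            print(f"  {key:<13} (not validated)")
        else:
            print(f"  {key:<13} V={cv['V']:.0f} P={cv['P']:.4f} "
                  f"accepted={cv['accepted']}")

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "road_use": {k: (v.to_dict() if v else None) for k, v in res["road_use"].items()},
        "distance": {k: (v.to_dict() if v else None) for k, v in res["distance"].items()},
        "crossvalidation": res["crossvalidation"],
    }
    with open(outdir / "ssf_fits.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return 0


if __name__ == "__main__":
    sys.exit(main())
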