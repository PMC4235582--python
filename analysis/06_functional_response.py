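"""Fit the home-range-scale functional response of gravel road use.

Per data set: availability = % of home-range land area within 30 m of a
gravel road; use = % of hourly fixes within 30 m. Ordinary least squares of
use on availability per reproductive status (with home-range size, median
Julian date and sex as eliminable covariates) and the slope-vs-1 /
intercept-vs-0 t-tests. Proportional use would give slope 1, intercept 0.
Writes results/fr_records.csv (scatter data) and results/fr_fits.json.
"""

import argparse
import importlib.util
import json
import sys
import warnings
from pathlib import Path

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

    from wolfroads.pipeline import fr_stage

    warnings.filterwarnings("ignore")
    cfg, study, meta, clustered, _seeds = _clmod.prepare(args.seed)
    res = fr_stage(study, clustered, meta, cfg)

    rec = res["records"]
    print(rec.groupby("reproduction")[["availability_pct", "use_pct"]]
          .agg(["mean", "min", "max"]).round(2).to_string())
    for status, fr in res["fits"].items():
        if fr is None:
            print(f"{status}: not fitted (too few data sets)")
            continue
        print(
            f"{status}: slope={fr['slope']:.3f}+/-{fr['slope_se']:.3f} "
            f"intercept={fr['intercept']:.3f} R2={fr['r2']:.2f} "
            f"P(slope)={fr['slope_p']:.3f} P(slope=1)={fr['p_slope_vs_1']:.3f}"
        )

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    rec.to_csv(outdir / "fr_records.csv", index=False)
    payload = {
        k: (
            None
            if v is None
            else {kk: (vv.to_dict() if hasattr(vv, "to_dict") else vv)
                  for kk, vv in v.items() if kk != "trace"}
        )
        for k, v in res["fits"].items()
    }
    with open(outdir / "fr_fits.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return 0


if __name__ == "__main__":
    sys.exit(main())
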