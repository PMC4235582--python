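"""Fit the travel-speed mixed model.

Speed (km/h) of half-hourly steps as a function of the 3-state road
variable in interaction with reproductive status and time of day, nested
random intercepts (data set in territory), backward elimination at
alpha = 0.05, Nakagawa R2. Prints the coefficient table (reference cell:
on-road, nonbreeding, day) and per-road-state summaries, and writes
results/speed_fit.json.
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

    from wolfroads.pipeline import speed_stage

    warnings.filterwarnings("ignore")
    cfg, study, meta, _clustered, _seeds = _clmod.prepare(args.seed)
    res = speed_stage(study, meta, cfg)

    print(res["fit"].summary())
    print(res["summary"].to_string(index=False))
    ratio = res["summary"].attrs.get("on_off_ratio")
    print(f"on/off speed ratio: {ratio:.2f}")
    print(f"R2 marginal {res['r2_marginal']:.3f}, conditional {res['r2_conditional']:.3f}")

    from wolfroads.speed_model import predicted_speed

    for combo in (("on", "breeding", "Night"), ("on", "nonbreeding", "Day")):
        print(f"predicted mean speed {combo}: "
              f"{predicted_speed(res['fit'], *combo):.2f} km/h")

    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "speed_fit.json", "w") as fh:
        json.dump(
            {
                "fit": res["fit"].to_dict(),
                "r2_marginal": res["r2_marginal"],
                "r2_conditional": res["r2_conditional"],
                "summary": res["summary"].to_dict(orient="records"),
                "on_off_ratio": ratio,
            },
            fh, indent=2, default=str,
        )
    return 0


if __name__ == "__main__":
    sys.exit(main())
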