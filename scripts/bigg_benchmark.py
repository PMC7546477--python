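#!/usr/bin/env python
"""Optimization-count benchmark on genome-scale models (download-gated).

Counts the linear-program solves needed to simulate single organisms and
communities to t = 5 on an M9-style medium, comparing basis reuse with
the direct Euler baseline.  Genome-scale models (e.g. iJR904, iND750,
iJN746, iEK1008) are NOT bundled: supply previously downloaded JSON GEMs
via --models-dir, or pass --download to fetch them from the BiGG model
repository (requires network access; nothing is downloaded without this
flag).

Example:
    python scripts/bigg_benchmark.py --models-dir models/ iJR904 iND750
"""

from __future__ import annotations

import argparse
import itertools
import sys
from pathlib import Path

BIGG_URL = "http://bigg.ucsd.edu/static/models/{model}.json"


def fetch(model_id: str, dest: Path) -> Path:
    import urllib.request

    path = dest / f"{model_id}.json"
    if not path.exists():
        print(f"downloading {model_id} ...", file=sys.stderr)
        urllib.request.urlretrieve(BIGG_URL.format(model=model_id), path)
    return path


def main():
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("model_ids", nargs="*", default=[],
                    help="model identifiers (JSON files named <id>.json)")
    ap.add_argument("--models-dir", type=Path, default=Path("models"))
    ap.add_argument("--download", action="store_true",
                    help="fetch missing models from the public model repository")
    ap.add_argument("--medium", type=Path, default=None,
                    help="CSV metabolite_id,concentration (default: uniform 10)")
    ap.add_argument("-T", "--horizon", type=float, default=5.0)
    ap.add_argument("--dt", type=float, default=0.01)
    ap.add_argument("--x0", type=float, default=0.3)
    ap.add_argument("--pairs", action="store_true", help="also run all pairs")
    args = ap.parse_args()

    if not args.model_ids:
        ap.print_help()
        print("\nno models requested; nothing to do (models are not bundled "
              "and are only fetched with --download)", file=sys.stderr)
        sys.exit(2)

    paths = []
    for mid in args.model_ids:
        p = args.models_dir / f"{mid}.json"
        if not p.exists():
            if not args.download:
                print(f"missing {p}; re-run with --download to fetch it",
                      file=sys.stderr)
                sys.exit(2)
            args.models_dir.mkdir(parents=True, exist_ok=True)
            p = fetch(mid, args.models_dir)
        paths.append(p)

    from dfbasis.dynamics import SimSettings, simulate
    from dfbasis.experiments import run_direct_baseline
    from dfbasis.gem_io import load_gem, load_medium

    loaded = [load_gem(p) for p in paths]
    combos = [(i,) for i in range(len(loaded))]
    if args.pairs:
        combos += list(itertools.combinations(range(len(loaded)), 2))

    print(f"{'combination':40s} {'basis_reuse':>12s} {'direct_euler':>12s}")
    for combo in combos:
        models = [loaded[i][0] for i in combo]
        bounds = [loaded[i][1] for i in combo]
        medium = (load_medium(args.medium) if args.medium
                  else {mid: 10.0 for m in models for mid in m.metabolite_ids})
        label = "+".join(m.species_id for m in models)
        res = simulate(models, medium, [args.x0] * len(models), args.horizon,
                       settings=SimSettings(dt=args.dt), bounds=bounds)
        base = run_direct_baseline(models, medium, [args.x0] * len(models),
                                   args.horizon, args.dt, bounds=bounds)
        print(f"{label:40s} {res.optimization_count['total']:>12d} "
              f"{base.optimization_count['total']:>12d}")


if __name__ == "__main__":
    main()
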