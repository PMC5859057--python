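"""Switch-off sensitivity checks of the synthetic-data mechanisms.

Two falsification runs at reduced replicate counts: (a) a single-mode
optimum distribution must lose the bimodality verdict; (b) flat response
tolerances (no narrowing toward the extremes) must lose the significant
P-side width decrease.  Writes results/sensitivity.json.
"""

import json
from pathlib import Path

from npniche.modality import modality_test
from npniche.niche import niche_estimates, select_pool
from npniche.nullmodel import build_ensemble
from npniche.simulate import SynthConfig, generate_dataset
from npniche.tradeoff import subset_slopes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = {}

    ds, _ = generate_dataset(SynthConfig(mode_weights=(1.0, 0.0), seed=21))
    pool = select_pool(ds.matrix, 10)
    est = niche_estimates(ds.matrix, ds.log_np(), pool)
    res = modality_test(est["position"].to_numpy(), n_sim=300, seed=33, n_restarts=8)
    out["single_mode_truth"] = {
        "verdict_005": res.verdict[0.05],
        "minus2lnLambda": res.minus2lnLambda,
    }
    print(f"single-mode truth -> verdict {res.verdict[0.05]} "
          f"(-2lnLambda={res.minus2lnLambda:.2f})")

    ds, _ = generate_dataset(SynthConfig(tolerance_extremity_slope=0.0, seed=22))
    pool = select_pool(ds.matrix, 10)
    x = ds.log_np()
    est = niche_estimates(ds.matrix, x, pool)
    ens = build_ensemble(ds.matrix, x, pool, n_replicates=300, master_seed=22)
    slopes = subset_slopes(est, ens, grand_mean=float(x.mean()))
    out["flat_tolerance_truth"] = {
        side: {"slope_real": s.slope_real, "p_value": s.p_value}
        for side, s in slopes.items()
    }
    for side, s in slopes.items():
        print(f"flat tolerances, {side}: slope {s.slope_real:.3f}, p {s.p_value:.3f}")

    path = ROOT / "results" / "sensitivity.json"
    path.parent.mkdir(exist_ok=True)
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
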