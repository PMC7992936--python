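#!/usr/bin/env python
"""Monte-Carlo sweep: censoring attenuation of the observed effect size.

Holds the latent standardized effect fixed at 0.5 and moves the latent
control mean across the scale (position 0.55 ... 0.95 of the worst-to-best
range); 500 replicate trials per grid point. The mean observed d falls as
the mean approaches the ceiling — the mechanism by which bounded scales
shrink observed-to-estimated effect-size ratios at long follow-up.

Writes ``results/attenuation.csv``.
"""

from pathlib import Path

from powergap.synthetic import attenuation_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sweep = attenuation_summary(
        positions=(0.55, 0.65, 0.75, 0.85, 0.95),
        delta_over_sigma=0.5,
        reps=500,
        seed=101,
    )
    RESULTS.mkdir(parents=True, exist_ok=True)
    out = RESULTS / "attenuation.csv"
    sweep.to_csv(out, index=False)
    print(sweep.to_string(index=False,
                          float_format=lambda v: f"{v:.3f}"))
    drop = 100 * (1 - sweep["mean_d_obs"].iloc[-1] / sweep["mean_d_obs"].iloc[0])
    print(f"\nmean observed d falls {drop:.0f} % from mid-scale to the "
          "near-ceiling position at a fixed latent effect of 0.5 SD")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
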