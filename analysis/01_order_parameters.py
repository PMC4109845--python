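"""Order parameters of a disordered-but-correlated synthetic swarm.

Generates a swarm whose velocity fluctuations are spatially correlated but
carry no net collective mode, measures polarization, rotational and
dilatational order per frame, and compares them with the Monte-Carlo band
of a completely uncorrelated system of the same size.  Finding: all three
order parameters sit at the uncorrelated-system scale — order is absent
even though correlation (script 02) is strong.
"""

import argparse
from pathlib import Path

from midgeswarm.fixtures import correlated_trajectory
from midgeswarm.pipeline import order_parameter_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    traj = correlated_trajectory(
        n=150, corr_length=0.2, n_frames=20, seed=args.seed, event_id="synthetic-swarm"
    )
    table = order_parameter_table(traj, null_samples=300, seed=args.seed + 1)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "order_parameters.csv", index=False)
    mean_pol = table["polarization"].mean()
    band = table["null_mean_polarization"].iloc[0]
    band_sd = table["null_sd_polarization"].iloc[0]
    print(f"frames analysed: {len(table)}, N = {int(table['n'].median())}")
    print(
        f"polarization {mean_pol:.3f} vs uncorrelated band "
        f"{band:.3f} +- {band_sd:.3f}"
    )
    print(
        f"rotational {table['rotational'].mean():.3f}, "
        f"dilatational {table['dilatational'].mean():.3f}"
    )
    print("-> no collective order beyond the uncorrelated-system scale")


if __name__ == "__main__":
    main()
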