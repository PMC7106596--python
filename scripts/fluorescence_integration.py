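"""Optional integration run on real fluorescence-dye descriptor tables.

Given the fluorescence emission-wavelength descriptor files (a ~392-sample
training table and a ~81-sample test table; CSV, first column sample id,
target column holding the emission wavelength in nm), fits the four
level-0 ensembles and the three blend variants and REPORTS train/test
R² and RMSE. Nothing is asserted: real-data results depend on stochastic
hyperparameter tuning and are for inspection only.

Usage:
    python scripts/fluorescence_integration.py \
        --train train.csv --test test.csv --target lambda_em [--tune]
"""

from __future__ import annotations

import argparse

from qsprblend import Level0Spec, read_table, run_experiment, tune_level0
from qsprblend.level0 import KINDS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--train", required=True)
    parser.add_argument("--test", required=True)
    parser.add_argument("--target", default="y", help="target column (wavelength, nm)")
    parser.add_argument("--solvent-column", default=None,
                        help="categorical solvent column, if present")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--tune", action="store_true",
                        help="randomized 5-fold CV search per level-0 model")
    args = parser.parse_args()

    cat = [args.solvent_column] if args.solvent_column else None
    train = read_table(args.train, target_column=args.target,
                       categorical_columns=cat, task="regression")
    test = read_table(args.test, target_column=args.target,
                      categorical_columns=cat, task="regression")
    print(f"train: {train.n_samples} x {train.n_features}; "
          f"test: {test.n_samples} x {test.n_features}")

    specs = [Level0Spec(kind=k, random_state=args.seed) for k in KINDS]
    if args.tune:
        specs = [
            tune_level0(train, s, n_iter=10, k=5, seed=args.seed) for s in specs
        ]
        for s in specs:
            print(f"tuned {s.kind}: {s.hyperparameters}")

    result = run_experiment(train, test, specs=specs, seed=args.seed)
    print(result.table.round(3).to_string())


if __name__ == "__main__":
    main()
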