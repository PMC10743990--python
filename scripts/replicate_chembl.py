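"""Optional full-scale replication on local ChEMBL exports.

Re-derives the published study from locally downloaded bioactivity tables:
curated compound counts, per-model test-set metrics for the four selected
Morgan-fingerprint models, and the consensus combination ranking.  Expects
two CSV exports for the GSK3beta target (UniProt P49841) from ChEMBL
release 30 — IC50 records for training and Ki records for testing — with
columns (compound_id, smiles, value, units, type, relation).  No network
access is used; you must download the exports yourself.

Note: the published per-model accuracies additionally depend on tuned
hyperparameter values that were never printed, so the numbers here are
replication goals, not exact targets.

Usage:
    python scripts/replicate_chembl.py --train-csv gsk3b_ic50.csv \
        --test-csv gsk3b_ki.csv --out results/replication.json
"""

from __future__ import annotations

import argparse
import json
import os
import sys


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--train-csv", required=True, help="IC50 activity export")
    parser.add_argument("--test-csv", required=True, help="Ki activity export")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results/replication.json")
    args = parser.parse_args()

    for path in (args.train_csv, args.test_csv):
        if not os.path.exists(path):
            print(f"error: input file not found: {path}", file=sys.stderr)
            return 2

    import consensusvs as cvs
    from consensusvs.consensus import enumerate_combinations, rank_combinations
    from consensusvs.modeling import ModelSpec, features_for, grid_search, train
    from consensusvs.workflow_io import read_activity_csv

    train_ds, train_audit = cvs.build_dataset(
        read_activity_csv(args.train_csv), "train"
    )
    test_ds, test_audit = cvs.build_dataset(read_activity_csv(args.test_csv), "test")
    report: dict = {
        "curated": {
            "n_unique_train_compounds": len(train_ds) ,
            "train_active": train_ds.n_active(),
            "train_inactive": train_ds.n_inactive(),
            "test_active": test_ds.n_active(),
            "test_inactive": test_ds.n_inactive(),
        }
    }

    X_train = features_for(train_ds, "morgan")
    X_test = features_for(test_ds, "morgan")
    models = []
    report["models"] = {}
    for algorithm in ("RF", "SVM", "KNN", "MLP"):
        gs = grid_search(
            train_ds, algorithm, "morgan", seed=args.seed, features=X_train
        )
        spec = ModelSpec.create(algorithm, "morgan", gs.best_params, seed=args.seed)
        model = train(spec, train_ds, features=X_train)
        models.append(model)
        rep = cvs.evaluate(model.predict_labels(X_test), test_ds.labels)
        report["models"][spec.name] = {
            "hyperparameters": {k: str(v) for k, v in gs.best_params.items()},
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "recall": rep.recall,
        }

    combos = enumerate_combinations(models)
    ranked = rank_combinations(combos, X_test, test_ds.labels)
    best, best_rep = ranked[0]
    report["consensus"] = {
        "n_combinations": len(combos),
        "best": best.name,
        "accuracy": best_rep.accuracy,
        "precision": best_rep.precision,
        "recall": best_rep.recall,
    }

    os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2)
    print(json.dumps(report, indent=2))
    return 0


if __name__ == "__main__":
    sys.exit(main())
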