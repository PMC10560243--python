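"""Compare the seven clinical-score estimators by 5-fold cross-validation.

Builds the seven configurations (two linear models on selected features, a
random forest on all progressing features, and linear/forest pairs on PCA
factors of the progressing and full feature sets), scores each by mean RMSE
over a shared random 5-fold split, and reports the winner. Also contrasts
the winner with single-feature baselines.
"""

import json
from pathlib import Path

from gaitprog.io import read_cohort_dir
from gaitprog.models import default_model_specs, univariate_baselines
from gaitprog.preprocess import preprocess
from gaitprog.selection import find_progressing_features, forward_select
from gaitprog.validation import compare_models, make_cv_plan

ROOT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    cohort, scores = read_cohort_dir(ROOT / "cohort")
    pre, _ = preprocess(cohort, scores)
    rep = find_progressing_features(pre)
    pool = rep.progressing
    rank = {f: i for i, f in enumerate(rep.table.index)}
    fsel = forward_select(pre, pool, pool[0], candidate_rank=rank)

    specs = default_model_specs(pool, fsel.consensus, pre.feature_names,
                                n_estimators=300, seed=seed)
    plan = make_cv_plan(pre, n_folds=5, split_unit="row", seed=seed)
    comp = compare_models(pre, specs, plan)

    print("cross-validated RMSE (mean over 5 folds, sample std):")
    for mid, row in comp.table.iterrows():
        star = " <- winner" if mid == comp.winner_id else ""
        print(f"  model {mid}: {row['rmse_mean']:.2f} ({row['rmse_std']:.2f}) "
              f"[{row['label'].split(': ')[1]}, {row['n_inputs']} inputs]{star}")

    uni = univariate_baselines(pre, pool, plan)
    print(f"best single-feature RMSE: {uni.iloc[0]['rmse_mean']:.2f} "
          f"({uni.iloc[0]['feature']}) — the multivariate winner is "
          f"{'better' if comp.table.loc[comp.winner_id, 'rmse_mean'] < uni.iloc[0]['rmse_mean'] else 'worse'}")

    payload = {
        "winner_model_id": comp.winner_id,
        "models": {str(m): {"rmse_mean": r["rmse_mean"], "rmse_std": r["rmse_std"]}
                   for m, r in comp.table.iterrows()},
        "best_univariate_rmse": float(uni.iloc[0]["rmse_mean"]),
    }
    (ROOT / "model_comparison.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    uni.to_csv(ROOT / "univariate_baselines.csv", index=False)


if __name__ == "__main__":
    main()
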