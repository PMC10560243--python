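"""Preprocess the simulated cohort: exclusion, imputation, normalisation.

Reads results/cohort/ (run 01_simulate_cohort.py first), applies the cohort
construction rules — exclude participants with >2 consecutive missed visits,
interpolate remaining gaps, assemble clinical totals, divide stride length
by height, relabel Left/Right as Ipsilateral/Contralateral — and writes the
complete wide matrix under results/preprocessed/.
"""

from pathlib import Path

from gaitprog.io import read_cohort_dir
from gaitprog.preprocess import preprocess

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort, scores = read_cohort_dir(ROOT / "cohort")
    pre, log = preprocess(cohort, scores)

    out = ROOT / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    pre.values.to_csv(out / "values.csv")
    pre.scores.to_csv(out / "clinical_totals.csv")
    pre.imputed.to_csv(out / "imputed_mask.csv")
    log.to_csv(out / "exclusion_log.csv")

    n_imputed = int(pre.imputed.any(axis=1).sum())
    print(f"retained {pre.values.index.get_level_values(0).nunique()} of "
          f"{len(log)} participants ({int(log['excluded'].sum())} excluded)")
    print(f"imputed {n_imputed} participant-visit rows")
    print(f"no Left/Right tokens remain: "
          f"{not any(c.startswith(('Left_', 'Right_')) for c in pre.values.columns)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
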