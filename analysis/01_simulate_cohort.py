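"""Simulate the study cohort and summarise its structure.

Generates the default synthetic cohort — 74 people with Parkinson's followed
over 7 visits at 3-month intervals, 122 gait/sway features, 29 of them
coupled to a drifting latent severity — and writes it with its ground truth
under results/cohort/.
"""

from pathlib import Path

from gaitprog.simulate import CohortConfig, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    cfg = CohortConfig(seed=seed)
    cohort, scores, truth = generate_cohort(cfg)
    write_cohort(cohort, scores, truth, OUT / "cohort")

    obs = cohort.observed_visits()
    n_missed = cfg.n_participants * cfg.n_visits - sum(len(v) for v in obs)
    totals = (
        scores.items[~scores.items["item_id"].isin(["3.1", "3.2"])]
        .groupby(["participant_id", "visit"])["item_value"]
        .sum()
    )
    print(f"cohort: {cfg.n_participants} participants x {cfg.n_visits} visits, "
          f"{cfg.n_features} features ({cfg.n_progressing} progressing)")
    print(f"missed visits: {n_missed}")
    print(f"clinical total score: mean {totals.mean():.1f}, sd {totals.std():.1f} "
          f"(target regime: ~24 +/- 12)")
    print(f"wrote {OUT / 'cohort'}")


if __name__ == "__main__":
    main()
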