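"""Bootstrap regression of CV parameters on BCG/PPG features.

Reads the per-beat feature tables written by 04_extract_features.py, applies
the windowed-MAD feature cleaning and the period/subject exclusion rules,
locates the per-period extremum windows, expands them with the parametric
bootstrap, fits all 136 univariate/bivariate models per target, evaluates
them on the representative points, and writes the ranked per-subject models
plus a cohort summary (best feature set per target, mean +- SE of the
evaluation correlation).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from limbbcg.config import PipelineConfig, derive_seed
from limbbcg.pipeline import SOURCES, clean_features
from limbbcg.regression import (apply_exclusions, cohort_summary,
                                evaluate_models, fit_all_regressions,
                                make_representatives, merge_bootstrap,
                                models_to_frame)
from limbbcg.synth.protocol import CV_PARAMS, PERIOD_LABELS


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = PipelineConfig(master_seed=args.seed)

    for source in SOURCES:
        path = args.out / f"features_{source}.csv"
        if not path.exists():
            print(f"{path} missing; run 04_extract_features.py first")
            continue
        table = pd.read_csv(path)
        frames, fracs = [], {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sid, sub in table.groupby("subject_id"):
                cleaned, clean_fracs = clean_features(sub, cfg)
                frames.append(cleaned)
                for per in PERIOD_LABELS:
                    fracs[(sid, per)] = clean_fracs.get(per, 1.0)
            retained = apply_exclusions(fracs, cfg.removal_fraction_threshold,
                                        cfg.min_periods)
            cleaned = pd.concat(frames, ignore_index=True)
            keep = [(s, p) in retained for s, p in
                    zip(cleaned.subject_id, cleaned.period)]
            cleaned = cleaned[pd.Series(keep).to_numpy()]

            model_frames = []
            for sid, sub in cleaned.groupby("subject_id"):
                reps = make_representatives(sub, sid, width=cfg.window_width)
                for target in CV_PARAMS:
                    if sum(r.target == target for r in reps) < 3:
                        continue
                    boot = merge_bootstrap(
                        reps, target, cfg.n_bootstrap, cfg.window_width,
                        derive_seed(args.seed, f"{source}:{sid}:{target}"))
                    models = fit_all_regressions(
                        boot, target, max_order=cfg.max_model_order)
                    models = evaluate_models(models, reps, cfg.r_threshold)
                    model_frames.append(models_to_frame(models, sid))
        all_models = pd.concat(model_frames, ignore_index=True)
        all_models.to_csv(args.out / f"models_{source}.csv", index=False,
                          float_format="%.6g")
        summary = cohort_summary(all_models)
        summary.to_csv(args.out / f"summary_{source}.csv", index=False,
                       float_format="%.6g")
        print(f"== {source} BCG: best feature set per target "
              f"(eval r, mean +- SE over subjects)")
        for _, row in summary.iterrows():
            print(f"  {row.target:>3} order {row.order}: {row.predictors:<22}"
                  f" r = {row.eval_r_mean:.2f} +- {row.eval_r_se:.2f}"
                  f" (n={row.n_subjects})")


if __name__ == "__main__":
    main()
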