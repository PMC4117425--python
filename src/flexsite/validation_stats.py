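"""Validation statistics over printed druggability tables.

Two analyses are reproduced from printed inputs that ship with the
package:

* the protein-protein interaction validation set (27 structures over six
  targets, each assigned *druggable* or *difficult* from clinical
  precedent) with false-positive / false-negative rates of the flexible
  druggability call, and
* the score-variation comparison on targets with known binding-site
  flexibility: per-target Variation = (max - min) / mean of the target's
  scores across its crystal structures, in percent, for a docking-hit-rate
  method and for the flexibility-modeling Dscore+ (IL-2 and HPV E2
  flexibility scores come from calculations run without the rigid-gate
  cut-off, as footnoted in the source table).

Per-structure scores and volumes in these tables are *inputs* (they
originate from a proprietary scorer); only the statistics are recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .decision import DecisionConfig

__all__ = [
    "load_table1",
    "load_table2",
    "fp_fn_rates",
    "variation",
    "variation_summary",
    "table2_variations",
    "validation_report",
]


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _data_path(name: str):
    return resources.files("flexsite").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """PPI validation rows; '*' (not applicable: the rigid score missed the
    gate) parses to NaN."""
    with resources.as_file(_data_path("table1_ppi.tsv")) as p:
        return pd.read_csv(p, sep="\t", na_values=["*"])


def load_table2() -> pd.DataFrame:
    """Per-structure scores of the flexible-pocket comparison set."""
    with resources.as_file(_data_path("table2_flexible_pockets.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def fp_fn_rates(rows: pd.DataFrame,
                cfg: DecisionConfig | None = None) -> tuple:
    """(FP%, FN%) of the flexible druggability call over validation rows.

    A row is predicted positive when its flexible Dscore+ meets the
    flexible gate and its flexible volume lies in the drug-like range;
    not-applicable rows are predicted negative.  FP% is the fraction of
    positives that are assigned difficult; FN% the fraction of assigned
    druggable rows predicted negative.  Both are rounded to whole percent.
    """
    cfg = cfg or DecisionConfig()
    lo, hi = cfg.druglike_volume
    score = rows["flex_score"].astype(float)
    vol = rows["flex_volume"].astype(float)
    positive = (score >= cfg.flexible_gate) & (vol >= lo) & (vol <= hi)
    positive = positive.fillna(False)
    druggable = rows["assigned"].str.strip() == "druggable"

    n_pos = int(positive.sum())
    fp = _round_half_away(
        100.0 * float((positive & ~druggable).sum()) / n_pos
    ) if n_pos else 0
    n_drug = int(druggable.sum())
    fn = _round_half_away(
        100.0 * float((druggable & ~positive).sum()) / n_drug
    ) if n_drug else 0
    return fp, fn


def variation(scores) -> int:
    """Per-target Variation: (max - min) / mean x 100, rounded to whole
    percent."""
    x = np.asarray(list(scores), dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("variation needs at least two finite scores")
    mean = x.mean()
    if mean == 0:
        raise ValueError("variation undefined for zero-mean scores")
    return _round_half_away(100.0 * (x.max() - x.min()) / mean)


def variation_summary(variations) -> tuple:
    """(median%, sample std%) of per-target variations, both rounded to
    whole percent (the spread uses the n-1 sample standard deviation)."""
    v = np.asarray(list(variations), dtype=float)
    if len(v) < 2:
        raise ValueError("summary needs at least two targets")
    return _round_half_away(float(np.median(v))), _round_half_away(
        float(np.std(v, ddof=1))
    )


def table2_variations(rows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-target Variation for both methods, in source-table target order."""
    rows = rows if rows is not None else load_table2()
    out = []
    for target in rows["target"].drop_duplicates():
        sub = rows[rows["target"] == target]
        out.append(
            {
                "target": target,
                "n_structures": len(sub),
                "variation_docking": variation(sub["dock_hit_rate"]),
                "variation_flexible": variation(sub["flex_dscore_plus"]),
            }
        )
    return pd.DataFrame(out)


def validation_report(cfg: DecisionConfig | None = None) -> dict:
    """The full printed-table validation block as one dictionary."""
    cfg = cfg or DecisionConfig()
    fp, fn = fp_fn_rates(load_table1(), cfg)
    var = table2_variations()
    med_d, std_d = variation_summary(var["variation_docking"])
    med_f, std_f = variation_summary(var["variation_flexible"])
    return {
        "ppi_false_positive_percent": fp,
        "ppi_false_negative_percent": fn,
        "variation_per_target": var.to_dict(orient="records"),
        "docking_variation_median_percent": med_d,
        "docking_variation_std_percent": std_d,
        "flexible_variation_median_percent": med_f,
        "flexible_variation_std_percent": std_f,
    }
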