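"""End-to-end screen analysis: dataset -> endpoints -> tests -> hits -> LOELs.

Thin orchestration over the per-stage modules, one condition
(chemical x worm type x day) at a time:

1. compile the per-animal endpoint table;
2. lethality screen (Fisher + BH) and lethal-concentration exclusion;
3. endpoint-class-specific testing against the in-plate control;
4. relevancy cutoffs from the control bank, pooled and per-run group
   summaries, consistency and concentration-dependence filters;
5. hit records and the LOEL matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd

from . import behavior_endpoints as be
from . import hit_calling as hc
from . import screening_stats as ss
from .synthetic_plate import ScreenDataset

__all__ = ["ConditionResult", "ScreenAnalysis", "cutoffs_from_bank", "analyze_screen"]


@dataclass
class ConditionResult:
    """Everything the pipeline derives for one chemical x worm type x day."""

    chemical: str
    worm_type: str
    day: int
    lethal_set: Set[float]
    test_results: pd.DataFrame
    hits: pd.DataFrame
    loel: pd.Series

    @property
    def label(self) -> str:
        return f"{self.chemical}|{self.worm_type}|d{self.day}"


@dataclass
class ScreenAnalysis:
    conditions: List[ConditionResult]

    @property
    def loel_matrix(self) -> pd.DataFrame:
        return hc.loel_matrix({c.label: c.loel for c in self.conditions})

    def condition(self, worm_type: str, day: Optional[int] = None) -> ConditionResult:
        for c in self.conditions:
            if c.worm_type == worm_type and (day is None or c.day == day):
                return c
        raise KeyError(f"no condition for {worm_type!r}, day {day!r}")


def cutoffs_from_bank(
    bank: Sequence[ScreenDataset], worm_type: str, mode: str = "per_population"
) -> Dict[str, hc.RelevancyCutoff]:
    """Relevancy cutoffs for one worm type from a control bank."""
    tables = []
    for pop in bank:
        rec = pop.records[pop.records["worm_type"] == worm_type]
        ids = set(rec["record_id"])
        tables.append(
            be.compile_endpoints(
                rec,
                {k: v for k, v in pop.trajectories.items() if k in ids},
                {k: v for k, v in pop.heat_trajectories.items() if k in ids},
            )
        )
    return hc.compute_cutoffs(tables, mode=mode)


def analyze_screen(
    dataset: ScreenDataset,
    control_bank: Sequence[ScreenDataset],
    alpha: float = ss.ALPHA,
    seed: int = 0,
    cutoff_mode: str = "per_population",
    strict_consistency: bool = True,
    tails: Optional[Dict[str, str]] = None,
) -> ScreenAnalysis:
    """Run the full tiered analysis for every condition in a dataset."""
    tails = tails or be.DEFAULT_TAILS
    results: List[ConditionResult] = []
    for (worm, day), rec in dataset.records.groupby(["worm_type", "day"]):
        chemical = rec["chemical"].iloc[0]
        cutoffs = cutoffs_from_bank(control_bank, worm, cutoff_mode)
        table = be.compile_endpoints(
            rec,
            {k: v for k, v in dataset.trajectories.items()
             if k in set(rec["record_id"])},
            {k: v for k, v in dataset.heat_trajectories.items()
             if k in set(rec["record_id"])},
            tails=tails,
        )
        leth_results, lethal_set = ss.lethality_screen(rec, alpha=alpha)
        sub_results = ss.run_endpoint_screen(
            table, lethal_set, alpha=alpha, seed=seed, tails=tails
        )
        all_results = pd.concat(
            [leth_results, sub_results], ignore_index=True, sort=False
        )

        # group summaries: lethality over all animals at every concentration,
        # other endpoints over living animals at sublethal concentrations
        leth_rows = table[table["endpoint"] == "lethality"]
        sub_rows = table[
            (table["endpoint"] != "lethality")
            & ~table["concentration_uM"].isin(lethal_set)
        ]
        summary_input = pd.concat([leth_rows, sub_rows], ignore_index=True)
        pooled = hc.group_summaries(summary_input)
        per_run = hc.group_summaries(summary_input, by_run=True)

        hits = hc.assemble_hits(
            all_results, pooled, per_run, cutoffs,
            alpha=alpha, strict_consistency=strict_consistency,
        )
        loel = hc.compute_loel(hits)
        results.append(
            ConditionResult(
                chemical=chemical, worm_type=worm, day=int(day),
                lethal_set=lethal_set, test_results=all_results,
                hits=hits, loel=loel,
            )
        )
    return ScreenAnalysis(results)
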