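"""End-to-end report regeneration and input validation.

``run_study_report`` re-derives every summary number of the study from the
packaged tables — Bayesian classifications (pre and post functional
testing), per-gene carrier and per-variant recurrence frequencies, MOAT
groups and calcium competence flags, pooled clinical rates and the exact
ICSI vs ICSI-AOA comparisons — and checks them against the published
values, reporting any deviation.  Rates are carried as numerator/denominator
pairs; percentages are presentation only (2 dp, half-up).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from . import acmg, calcium, datasets, outcomes, variants

__all__ = [
    "PipelineConfig",
    "run_study_report",
    "validate_inputs",
    "load_evidence_json",
    "classification_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    bayes: acmg.BayesParams = acmg.BayesParams()
    detector: calcium.DetectorParams = calcium.DetectorParams()
    thresholds: calcium.AssayThresholds = calcium.AssayThresholds()
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def load_evidence_json(path) -> dict[str, list[acmg.EvidenceItem]]:
    """JSON of variant_id -> [{criterion, direction, strength}, ...]."""
    raw = json.loads(open(path).read() if isinstance(path, str) else path.read_text())
    return {
        vid: [
            acmg.EvidenceItem(
                item["criterion"],
                acmg.Direction(item["direction"]),
                acmg.Strength(item["strength"]),
            )
            for item in items
        ]
        for vid, items in raw.items()
    }


def classification_report(
    evidence_sets: dict[str, Sequence[acmg.EvidenceItem]],
    params: acmg.BayesParams | None = None,
) -> pd.DataFrame:
    """One classification row per variant id."""
    params = params or acmg.BayesParams()
    rows = []
    for vid, evidence in evidence_sets.items():
        res = acmg.classify(list(evidence), params)
        rows.append(
            {
                "variant_id": vid,
                "net_points": res.net_points,
                "posterior": res.posterior_3dp,
                "category": res.category.value,
                "vus_tier": res.vus_tier.value if res.vus_tier else "",
                "evidence_list": ";".join(e.criterion_code for e in res.evidence_used),
            }
        )
    return pd.DataFrame(rows)


# published summary values the report checks itself against
_GOLDEN = {
    "carrier_PLCZ1": (16, 55),
    "carrier_ACTL7A": (4, 27),
    "carrier_ACTL9": (1, 27),
    "recurrence_p.Ser500Leu": (8, 55),
    "recurrence_p.His233Leu": (5, 55),
    "fertilization_ICSI": (56, 498),
    "fertilization_ICSI_AOA": (199, 322),
    "blastocyst_ICSI_AOA": (94, 143),
    "hcg_ICSI": (5, 47),
    "hcg_ICSI_AOA": (21, 35),
    "lb_ICSI": (3, 47),
    "lb_ICSI_AOA": (13, 35),
}


def run_study_report(config: PipelineConfig | None = None) -> dict[str, object]:
    """Regenerate the study's summary numbers from the packaged tables.

    Returns a JSON-serialisable report with a ``deviations`` list, empty
    when every recomputed value matches its published counterpart.
    """
    config = config or PipelineConfig()
    fx = datasets.fixtures()
    deviations: list[str] = []

    # --- variant classification: posterior round-trips ---------------------
    table = fx["variants"]
    classifications = []
    for _, row in table.iterrows():
        entry = {"patient_id": row["patient_id"], "protein_change": row["protein_change"]}
        for phase in ("pre", "post"):
            reported = float(row[f"{phase}_posterior"])
            n = acmg.invert_posterior(reported, config.bayes)
            res = acmg.classification_with_points(n, config.bayes)
            entry[f"{phase}_points"] = n
            entry[f"{phase}_posterior"] = res.posterior_3dp
            entry[f"{phase}_category"] = res.category.value
            if res.posterior_3dp != reported:
                deviations.append(
                    f"{row['patient_id']} {row['protein_change']} {phase}: "
                    f"recomputed {res.posterior_3dp} != reported {reported}"
                )
        classifications.append(entry)

    # --- frequencies -------------------------------------------------------
    records = variants.filter_by_af(fx["variant_records"])
    ros = fx["rosters"]
    freq = {
        f"carrier_{gene}": variants.carrier_frequency(records, ros, gene)
        for gene in ("PLCZ1", "ACTL7A", "ACTL9")
    }
    for change in ("p.Ser500Leu", "p.His233Leu"):
        freq[f"recurrence_{change}"] = variants.variant_recurrence(records, ros, change)

    # --- MOAT groups and calcium competence --------------------------------
    moat = fx["moat"]
    moat_rows = []
    for _, row in moat.dropna(subset=["moat_two_cell"]).iterrows():
        res = outcomes.moat_group(int(row["moat_two_cell"]), int(row["moat_mii"]))
        label = str(row["moat_group_label"])
        entry = {
            "patient_id": row["patient_id"],
            "activation_rate_pct": variants.RateSummary(
                res.two_cell, res.mii, "MOAT"
            ).percent,
            "group": res.group,
        }
        if label not in ("", "nan") and str(res.group) not in label.split("-"):
            deviations.append(
                f"{row['patient_id']}: MOAT group {res.group} vs reported {label}"
            )
        for assay, col in ((calcium.Assay.MOCA, "moca_mean_axf"), (calcium.Assay.HOCA, "hoca_mean_axf")):
            if pd.notna(row.get(col)):
                entry[f"{assay.value.lower()}_competence"] = calcium.competence_flag(
                    float(row[col]), assay, config.thresholds
                ).value
        moat_rows.append(entry)

    # --- clinical outcomes --------------------------------------------------
    cycles = fx["cycles"]
    comparison = outcomes.compare_arms(cycles, alpha=config.alpha)
    agg = {}
    for arm in outcomes.Arm:
        selection = [c for c in cycles if c.arm is arm]
        suffix = arm.value
        agg[f"fertilization_{suffix}"] = outcomes.aggregate_rate(selection, "fertilization")
        agg[f"hcg_{suffix}"] = outcomes.aggregate_rate(selection, "hcg_per_cycle")
        agg[f"lb_{suffix}"] = outcomes.aggregate_rate(selection, "lb_per_cycle")
    agg["blastocyst_ICSI_AOA"] = outcomes.aggregate_rate(
        [c for c in cycles if c.arm is outcomes.Arm.ICSI_AOA], "blastocyst"
    )

    for key, (num, den) in _GOLDEN.items():
        summary = freq.get(key) or agg.get(key)
        if summary is None:
            continue
        if (summary.numerator, summary.denominator) != (num, den):
            deviations.append(
                f"{key}: recomputed {summary.numerator}/{summary.denominator} "
                f"!= published {num}/{den}"
            )

    def _rate(s: variants.RateSummary) -> dict[str, object]:
        return {"numerator": s.numerator, "denominator": s.denominator, "percent": s.percent}

    return {
        "classifications": classifications,
        "frequencies": {k: _rate(v) for k, v in freq.items()},
        "moat": moat_rows,
        "aggregates": {k: _rate(v) for k, v in agg.items()},
        "comparisons": {
            kind: {
                "icsi": _rate(d["icsi"]) if d["icsi"] else None,
                "icsi_aoa": _rate(d["icsi_aoa"]) if d["icsi_aoa"] else None,
                "p_value": d["p_value"],
                "significant": d["significant"],
            }
            for kind, d in comparison.items()
        },
        "deviations": deviations,
    }


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema diagnostics for input files; returns messages, never raises.

    ``paths`` maps kind ('variants' | 'cycles' | 'traces') to a file path.
    """
    diagnostics: list[str] = []
    for kind, path in paths.items():
        try:
            if kind == "variants":
                variants.parse_variant_table(path)
            elif kind == "cycles":
                df = pd.read_csv(path, keep_default_na=False)
                required = {"patient_id", "arm", "mii", "two_pn", "hcg_positive"}
                missing = required - set(df.columns)
                if missing:
                    diagnostics.append(f"{path}: missing column(s) {sorted(missing)}")
                    continue
                for idx, row in df.iterrows():
                    line = idx + 2
                    if int(row["two_pn"]) > int(row["mii"]):
                        diagnostics.append(
                            f"{path} line {line}: two_pn {row['two_pn']} > mii {row['mii']}"
                        )
                    for tok in str(row.get("outcomes", "")).split(";"):
                        if tok and tok not in outcomes.Outcome._value2member_map_:
                            diagnostics.append(
                                f"{path} line {line}: unknown outcome token {tok!r}"
                            )
            elif kind == "traces":
                calcium.read_traces_csv(path)
            else:
                diagnostics.append(f"unknown input kind {kind!r}")
        except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
            diagnostics.append(f"{path}: {exc}")
    return diagnostics
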