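"""Benchmark evaluation against experimental ddG values.

Experimental labels follow the convention: stabilising iff ddG >= 0
kcal/mol, destabilising otherwise.  Predicted labels use a strict
threshold: stabilising iff the predicted score > 0 (a score of exactly 0
counts as destabilising).  sigma is reported as the standard deviation of
(prediction - experiment) residuals; readers should note that other
definitions of a benchmark "standard error" exist.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import matthews_corrcoef

from .environment import Annotator, EnvironmentConfig
from .errors import MetricsError
from .esst import ESSTSet
from .scoring import ScoreWeights, predict
from .structure import ProteinStructure, parse_mutation

__all__ = [
    "BenchmarkRecord",
    "MetricsReport",
    "pearson_r",
    "classify_and_score",
    "run_benchmark",
    "evaluate_forward_reverse",
    "read_benchmark_csv",
]


@dataclass
class BenchmarkRecord:
    structure_ref: str
    chain: str
    mutation: str            # e.g. "L17A"
    exp_ddg: float           # kcal/mol
    pred_dds: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.exp_ddg):
            raise MetricsError(f"non-finite experimental ddG for {self.mutation}")


@dataclass
class MetricsReport:
    n: int
    pearson_r: float
    accuracy: float
    mcc: float
    sigma: float
    confusion: dict[str, int]
    n_excluded: int = 0
    mcc_degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": round(self.pearson_r, 4),
            "accuracy": round(self.accuracy, 4),
            "mcc": round(self.mcc, 4),
            "sigma": round(self.sigma, 4),
            "confusion": self.confusion,
            "n_excluded": self.n_excluded,
            "mcc_degenerate": self.mcc_degenerate,
            **self.extras,
        }


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise MetricsError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricsError("correlation undefined for zero-variance input")
    return float(_stats.pearsonr(x, y).statistic)


def classify_and_score(records: list[BenchmarkRecord]) -> MetricsReport:
    """Confusion matrix, accuracy, MCC, Pearson r and residual sigma.

    Records without a prediction are excluded and counted.  Positive class
    = stabilising.  A degenerate MCC (one-class predictor or one-class
    truth) is reported as 0 with a flag.
    """
    scored = [r for r in records if r.pred_dds is not None]
    n_excluded = len(records) - len(scored)
    if not scored:
        raise MetricsError("no records carry predictions")
    exp = np.array([r.exp_ddg for r in scored])
    pred = np.array([r.pred_dds for r in scored])
    exp_lab = exp >= 0.0
    pred_lab = pred > 0.0
    tp = int(np.sum(exp_lab & pred_lab))
    tn = int(np.sum(~exp_lab & ~pred_lab))
    fp = int(np.sum(~exp_lab & pred_lab))
    fn = int(np.sum(exp_lab & ~pred_lab))
    n = len(scored)
    accuracy = (tp + tn) / n
    degenerate = min(tp + fp, tn + fn, tp + fn, tn + fp) == 0
    mcc = 0.0 if degenerate else float(matthews_corrcoef(exp_lab, pred_lab))
    try:
        r = pearson_r(pred, exp)
    except MetricsError:
        r = float("nan")
    residuals = pred - exp
    sigma = float(np.std(residuals))
    return MetricsReport(
        n=n,
        pearson_r=r,
        accuracy=accuracy,
        mcc=mcc,
        sigma=sigma,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
        n_excluded=n_excluded,
        mcc_degenerate=degenerate,
    )


def read_benchmark_csv(path: str | Path) -> list[BenchmarkRecord]:
    """CSV with columns pdb, chain, mutation, exp_ddg; extras are ignored."""
    df = pd.read_csv(path)
    required = {"pdb", "chain", "mutation", "exp_ddg"}
    missing = required - set(df.columns)
    if missing:
        raise MetricsError(f"benchmark CSV lacks columns: {sorted(missing)}")
    return [
        BenchmarkRecord(row.pdb, str(row.chain), row.mutation, float(row.exp_ddg))
        for row in df.itertuples()
    ]


def run_benchmark(
    structures: dict[str, ProteinStructure],
    records: list[BenchmarkRecord],
    essts: ESSTSet,
    config: EnvironmentConfig | None = None,
    weights: ScoreWeights | None = None,
) -> tuple[MetricsReport, list[BenchmarkRecord]]:
    """Predict every record on its wildtype structure and score the set."""
    config = config or essts.config
    annotators: dict[str, Annotator] = {}
    out: list[BenchmarkRecord] = []
    for rec in records:
        structure = structures.get(rec.structure_ref)
        scored = BenchmarkRecord(rec.structure_ref, rec.chain, rec.mutation, rec.exp_ddg)
        if structure is not None:
            if rec.structure_ref not in annotators:
                annotators[rec.structure_ref] = Annotator(structure, config)
            mut = parse_mutation(rec.mutation, rec.chain, structure)
            pr = predict(
                structure, mut, essts, config, weights,
                keep_model=False, wt_annotator=annotators[rec.structure_ref],
            )
            scored.pred_dds = pr.dds
        out.append(scored)
    return classify_and_score(out), out


def evaluate_forward_reverse(
    wt_structures: dict[str, ProteinStructure],
    mutant_structures: dict[str, ProteinStructure],
    records: list[BenchmarkRecord],
    essts: ESSTSet,
    config: EnvironmentConfig | None = None,
    weights: ScoreWeights | None = None,
) -> tuple[MetricsReport, MetricsReport, int]:
    """Paired forward/reverse evaluation.

    Forward predictions run on the wildtype structures.  Reverse
    predictions run the inverted mutation on the supplied mutant
    structures (keyed ``"<structure_ref>:<mutation>"``) and are scored
    against the negated experimental ddG.  Records lacking a mutant
    structure are skipped from the reverse set and counted.
    """
    config = config or essts.config
    forward_report, forward_records = run_benchmark(
        wt_structures, records, essts, config, weights
    )
    reverse_records: list[BenchmarkRecord] = []
    skipped = 0
    annotators: dict[str, Annotator] = {}
    for rec in records:
        key = f"{rec.structure_ref}:{rec.mutation}"
        mutant = mutant_structures.get(key)
        if mutant is None:
            skipped += 1
            continue
        wt = wt_structures.get(rec.structure_ref)
        if wt is None:
            skipped += 1
            continue
        forward_mut = parse_mutation(rec.mutation, rec.chain, wt)
        inv = forward_mut.inverted()
        if key not in annotators:
            annotators[key] = Annotator(mutant, config)
        pr = predict(
            mutant, inv, essts, config, weights,
            direction="reverse", keep_model=False, wt_annotator=annotators[key],
        )
        reverse_records.append(
            BenchmarkRecord(
                rec.structure_ref, rec.chain, str(inv), -rec.exp_ddg, pr.dds
            )
        )
    reverse_report = classify_and_score(reverse_records)
    return forward_report, reverse_report, skipped


def write_metrics_json(report: MetricsReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
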