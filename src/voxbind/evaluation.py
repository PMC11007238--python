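"""Evaluation metrics and the repeated random-split benchmark protocol.

Performance is summarized by the Pearson correlation (PCC), Spearman rank
correlation (SPCC, average ranks on ties), root-mean-square error (RMSE)
and absolute error (AE; reported both per sample and as its mean, MAE)
between predicted and measured affinities.  The benchmark protocol draws
``repeats`` independent train/validation/test partitions of configured
sizes (100/29/13 by default) from the labelled set; indices not drawn in a
repeat are simply unused that repeat.  Per-repeat reports are averaged
arithmetically, with min/median/max dispersion alongside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("voxbind")

__all__ = [
    "MetricsReport", "SplitSpec", "compute_metrics", "make_splits",
    "aggregate_reports",
]


@dataclass
class MetricsReport:
    pcc: float
    spcc: float
    rmse: float
    mae: float
    ae: list[float] = field(default_factory=list)
    n: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass(frozen=True)
class SplitSpec:
    repeat_id: int
    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    master_seed: int

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError(f"repeat {self.repeat_id}: splits overlap")


def compute_metrics(truth, pred) -> MetricsReport:
    """PCC, SPCC, RMSE and per-sample absolute errors of a prediction set."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.all(t == t[0]) or np.all(p == p[0]):
        # correlations are undefined against a constant vector; the error
        # metrics remain meaningful
        logger.warning("constant input: correlations undefined, reported as NaN")
        pcc = spcc = float("nan")
    else:
        pcc = float(stats.pearsonr(t, p).statistic)
        spcc = float(stats.spearmanr(t, p).statistic)
    ae = np.abs(t - p)
    return MetricsReport(
        pcc=pcc,
        spcc=spcc,
        rmse=float(np.sqrt(np.mean((t - p) ** 2))),
        mae=float(ae.mean()),
        ae=ae.tolist(),
        n=int(t.size),
    )


def make_splits(
    n: int,
    sizes: tuple[int, int, int] = (100, 29, 13),
    repeats: int = 10,
    master_seed: int = 0,
) -> list[SplitSpec]:
    """Seeded repeated random partitions into train/val/test index lists.

    Repeat k draws from ``default_rng(master_seed + k)``; any indices
    beyond ``sum(sizes)`` are left unused for that repeat (e.g. 2 of 144
    under the default 100/29/13 sizes).
    """
    n_train, n_val, n_test = sizes
    total = n_train + n_val + n_test
    if total > n:
        raise ValueError(f"split sizes sum to {total} > dataset size {n}")
    leftover = n - total
    if leftover:
        logger.info(
            "make_splits: %d of %d indices unused per repeat", leftover, n
        )
    out = []
    for k in range(repeats):
        rng = np.random.default_rng(master_seed + k)
        perm = rng.permutation(n)
        out.append(
            SplitSpec(
                repeat_id=k,
                train=tuple(int(i) for i in perm[:n_train]),
                val=tuple(int(i) for i in perm[n_train:n_train + n_val]),
                test=tuple(int(i) for i in perm[n_train + n_val:total]),
                master_seed=master_seed,
            )
        )
    return out


def aggregate_reports(
    reports: list[MetricsReport],
) -> tuple[MetricsReport, pd.DataFrame]:
    """Mean metrics across repeats plus a min/median/max dispersion table."""
    if not reports:
        raise ValueError("no reports to aggregate")
    table = pd.DataFrame(
        [{"pcc": r.pcc, "spcc": r.spcc, "rmse": r.rmse, "mae": r.mae}
         for r in reports]
    )
    mean = MetricsReport(
        pcc=float(table["pcc"].mean()),
        spcc=float(table["spcc"].mean()),
        rmse=float(table["rmse"].mean()),
        mae=float(table["mae"].mean()),
        ae=[a for r in reports for a in r.ae],
        n=int(sum(r.n for r in reports)),
    )
    dispersion = table.agg(["min", "median", "max"])
    return mean, dispersion
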