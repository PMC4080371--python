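"""Batch experiments on random network pairs.

Runs one control mode over a seeded batch of random pairs and aggregates the
outcome the way the method's benchmark tables are laid out: average CPU time
per pair, ``#pos/#rep`` (pairs where the desired attractor was found / mean
iterations for those), and ``#neg/#rep`` (pairs proven to have no solution /
mean iterations).  Pairs undecided within the repeat budget are counted
separately.  Wall times are reported for information only; report *content*
(everything except the time columns) is a pure function of the seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .control import ControlProblemSpec, solve_control
from .generate import GeneratorConfig, random_bn_pair
from .scoring import ScoreConfig

__all__ = ["ExperimentReport", "run_experiment"]


@dataclass
class ExperimentReport:
    mode: str
    n: int
    m: int
    seed: int
    rows: pd.DataFrame  # per-pair: pair, status, iterations, max/min score, wall_time

    @property
    def aggregates(self) -> dict:
        rows = self.rows
        out = {"time": float(rows["wall_time"].mean())}
        for label, status in (
            ("pos", "found"), ("neg", "none_exists"), ("undecided", "repeat_limit")
        ):
            sub = rows[rows["status"] == status]
            out[f"#{label}"] = int(len(sub))
            out[f"#{label}_rep"] = (
                float(sub["iterations"].mean()) if len(sub) else float("nan")
            )
        return out

    def summary_table(self) -> pd.DataFrame:
        """The three-line summary in the benchmark-table layout."""
        agg = self.aggregates

        def ratio(label):
            if agg[f"#{label}"] == 0:
                return "0/-"
            return f"{agg[f'#{label}']}/{agg[f'#{label}_rep']:g}"

        return pd.DataFrame(
            {
                f"{self.n}/{self.m}": [
                    f"{agg['time']:.2f}",
                    ratio("pos"),
                    ratio("neg"),
                    ratio("undecided"),
                ]
            },
            index=["time(sec)", "#pos/#rep", "#neg/#rep", "#undecided/#rep"],
        )

    def content_frame(self) -> pd.DataFrame:
        """Per-pair rows without the hardware-dependent time column."""
        return self.rows.drop(columns=["wall_time"]).reset_index(drop=True)

    def to_text(self) -> str:
        header = f"# mode={self.mode} n={self.n} m={self.m} seed={self.seed}"
        body = self.rows.to_csv(sep="\t", index=False).rstrip("\n")
        summary = self.summary_table().to_csv(sep="\t").rstrip("\n")
        return f"{header}\n{body}\n#\n{summary}\n"


def run_experiment(
    mode: str,
    n: int,
    m: int,
    pairs: int,
    seed: int,
    K: int = 2,
    max_repeats: int = 20,
    alpha: float = 1.0,
    gamma: float = 1.0,
    theta: float | None = None,
    theta1: float | None = None,
    xi1: float | None = None,
    theta2: float | None = None,
    xi2: float | None = None,
    time_limit: float | None = None,
) -> ExperimentReport:
    """Solve ``pairs`` seeded random instances of one control mode.

    Per-pair seeds are spawned from one root ``seed`` so the batch is
    reproducible as a whole and each pair individually re-creatable.
    """
    child_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(pairs)
    ]
    records = []
    for p, child in enumerate(child_seeds):
        net1, net2 = random_bn_pair(GeneratorConfig(n=n, K=K, seed=child))
        spec = ControlProblemSpec(
            net1=net1,
            net2=net2,
            cfg=ScoreConfig.uniform(n, alpha, gamma),
            m=m,
            mode=mode,
            theta=theta,
            theta1=theta1,
            xi1=xi1,
            theta2=theta2,
            xi2=xi2,
            max_repeats=max_repeats,
            time_limit=time_limit,
        )
        t0 = time.perf_counter()
        sol = solve_control(spec)
        elapsed = time.perf_counter() - t0
        records.append(
            {
                "pair": p,
                "pair_seed": child,
                "n": n,
                "m": m,
                "status": sol.status,
                "iterations": sol.iterations,
                "max_score": sol.max_score,
                "min_score": sol.min_score,
                "wall_time": elapsed,
            }
        )
    return ExperimentReport(mode=mode, n=n, m=m, seed=seed, rows=pd.DataFrame(records))
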