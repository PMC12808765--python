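"""Drug-combination synergy from four-arm viability measurements.

A combination is synergistic when the combination's relative viability
falls below the product of the single-drug relative viabilities:
AB/C < (A/C)(B/C), i.e. combination index CI = (AB * C) / (A * B) < 1,
where C is the vehicle arm, A and B the single drugs and AB the
combination. CI is unit-free: rescaling all four arms leaves it
unchanged, and it is symmetric in A and B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError

ARMS = ("C", "A", "B", "AB")


@dataclass
class ViabilityRecord:
    """Replicate-averaged viability values of the four arms."""

    c: float
    a: float
    b: float
    ab: float

    def __post_init__(self):
        if self.c <= 0 or self.a <= 0 or self.b <= 0:
            raise DataError("C, A and B must be > 0")
        if self.ab < 0:
            raise DataError("AB must be >= 0")


def combination_index(rec: ViabilityRecord) -> float:
    """CI = (AB * C) / (A * B); CI < 1 indicates synergy."""
    return (rec.ab * rec.c) / (rec.a * rec.b)


def synergy_test(rec: ViabilityRecord, epsilon: float = 0.0) -> tuple[bool, float]:
    """Strict synergy call: AB/C < (A/C)(B/C) - epsilon.

    Returns (is_synergistic, combination index). epsilon defaults to 0
    (the bare strict inequality).
    """
    ci = combination_index(rec)
    return bool(rec.ab / rec.c < (rec.a / rec.c) * (rec.b / rec.c) - epsilon), ci


def synergy_table(plate: pd.DataFrame, epsilon: float = 0.0,
                  n_boot: int = 0, seed: int = 0) -> dict:
    """Summarize a plate table (columns arm, replicate, value).

    Replicates are averaged per arm before applying the synergy test.
    With ``n_boot`` > 0, a seeded bootstrap over replicates yields a
    percentile interval for the combination index.
    """
    missing = [a for a in ARMS if a not in set(plate["arm"])]
    if missing:
        raise DataError(f"missing plate arm(s): {missing}")
    means = plate.groupby("arm")["value"].mean()
    rec = ViabilityRecord(c=float(means["C"]), a=float(means["A"]),
                          b=float(means["B"]), ab=float(means["AB"]))
    is_syn, ci = synergy_test(rec, epsilon=epsilon)
    out = {
        "arm_means": {k: float(v) for k, v in means.items()},
        "combination_index": float(ci),
        "synergistic": is_syn,
    }
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        vals = {a: plate.loc[plate["arm"] == a, "value"].to_numpy() for a in ARMS}
        cis = np.empty(n_boot)
        for i in range(n_boot):
            m = {a: rng.choice(v, size=v.size, replace=True).mean()
                 for a, v in vals.items()}
            cis[i] = (m["AB"] * m["C"]) / (m["A"] * m["B"])
        out["ci_boot_interval"] = (float(np.quantile(cis, 0.025)),
                                   float(np.quantile(cis, 0.975)))
    return out
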