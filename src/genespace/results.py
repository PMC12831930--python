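"""Permutation/randomisation test results.

All Monte-Carlo p-values in this package use the add-one convention
``p = (1 + #extreme) / (n_perm + 1)`` so the smallest reportable p is
``1/(n_perm + 1)`` and p is never zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedStatisticError

TAILS = ("greater", "less", "two_sided")


def perm_p_value(observed: float, null_samples: np.ndarray, tail: str) -> float:
    """Add-one Monte-Carlo p-value for `observed` against `null_samples`."""
    null = np.asarray(null_samples, dtype=float)
    if tail == "greater":
        extreme = int(np.sum(null >= observed))
    elif tail == "less":
        extreme = int(np.sum(null <= observed))
    elif tail == "two_sided":
        centre = float(null.mean())
        extreme = int(np.sum(np.abs(null - centre) >= abs(observed - centre)))
    else:
        raise ValueError(f"unknown tail {tail!r}; expected one of {TAILS}")
    return (1 + extreme) / (null.size + 1)


@dataclass
class PermTestResult:
    """Observed statistic, its Monte-Carlo null summary and p-value."""

    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float
    tail: str
    seed: int
    null_samples: np.ndarray | None = field(default=None, repr=False)

    @property
    def z_score(self) -> float:
        """Standardised deviation (observed − null mean) / null sd."""
        if self.null_sd == 0:
            raise UndefinedStatisticError(
                "z-score undefined: null distribution has zero standard deviation"
            )
        return (self.observed - self.null_mean) / self.null_sd

    def to_dict(self) -> dict:
        d = {
            "statistic_name": self.statistic_name,
            "observed": float(self.observed),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "n_perm": int(self.n_perm),
            "p_value": float(self.p_value),
            "tail": self.tail,
            "seed": int(self.seed),
        }
        if self.null_samples is not None:
            d["null_samples"] = [float(x) for x in self.null_samples]
        try:
            d["z_score"] = float(self.z_score)
        except UndefinedStatisticError:
            d["z_score"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PermTestResult":
        samples = d.get("null_samples")
        return cls(
            statistic_name=d["statistic_name"],
            observed=float(d["observed"]),
            null_mean=float(d["null_mean"]),
            null_sd=float(d["null_sd"]),
            n_perm=int(d["n_perm"]),
            p_value=float(d["p_value"]),
            tail=d["tail"],
            seed=int(d["seed"]),
            null_samples=None if samples is None else np.asarray(samples, float),
        )


def permutation_result(
    statistic_name: str,
    observed: float,
    null_samples: np.ndarray,
    tail: str,
    seed: int,
    keep_null: bool = True,
) -> PermTestResult:
    """Assemble a :class:`PermTestResult` from an observed value and null draws."""
    null = np.asarray(null_samples, dtype=float)
    if null.size < 1:
        raise ValueError("need at least one null sample")
    return PermTestResult(
        statistic_name=statistic_name,
        observed=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        n_perm=int(null.size),
        p_value=perm_p_value(observed, null, tail),
        tail=tail,
        seed=int(seed),
        null_samples=null if keep_null else None,
    )


def write_result_json(result: PermTestResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_result_json(path) -> PermTestResult:
    with open(path, encoding="utf-8") as fh:
        return PermTestResult.from_dict(json.load(fh))
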