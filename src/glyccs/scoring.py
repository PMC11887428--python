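"""Boltzmann-weighted CCS scoring and assignment against reference values.

The final gas-phase assignment for a system is its global-minimum
conformer, but any conformer within ~3 kcal/mol of the minimum carries a
non-negligible Boltzmann population at 298 K, so the reported quantity is
the population-weighted average CCS over that window:

    RE_i = E_i - E_min
    P_i  = exp(-RE_i / kT) / sum_j exp(-RE_j / kT)
    CCS  = sum_i P_i * Omega_i       (i restricted to RE_i <= window)

An assignment is "successful" when the computed CCS agrees with the
experimental reference within 3% — the margin that absorbs typical
calibration error and inter-laboratory spread of drift-tube IM-MS.

Reference CCS values ship as CSV tables (stepped-field and single-field
drift-tube measurements, with the printed per-row percent errors of the
computed structures they accompany); user tables in the same schema are
accepted anywhere a bundled table is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BOLTZMANN_KCAL",
    "BoltzmannWeights",
    "boltzmann_weights",
    "weighted_ccs",
    "percent_error",
    "percent_difference",
    "load_reference_table",
    "reference_errors",
    "success_rate",
    "error_summary",
    "table1_percent_differences",
    "isomer_ordering",
    "AssignmentRow",
    "AssignmentReport",
]

BOLTZMANN_KCAL = 1.987204e-3  # kcal/(mol*K)
DEFAULT_TEMPERATURE = 298.0  # K
POPULATION_WINDOW_KCAL = 3.0  # inclusive
SUCCESS_THRESHOLD_PCT = 3.0

_POLICIES = ("averaged", "best_of_methods", "single", "stepped")


@dataclass
class BoltzmannWeights:
    relative_energies: np.ndarray  # kcal/mol, min must be 0
    temperature: float
    populations: np.ndarray  # mole fractions, sum to 1

    @property
    def n(self) -> int:
        return len(self.populations)


def boltzmann_weights(relative_energies, temperature: float = DEFAULT_TEMPERATURE) -> BoltzmannWeights:
    """Mole fractions P_i = exp(-RE_i/kT) / sum_j exp(-RE_j/kT).

    RE values must already be shifted so min(RE) = 0 (the ranking stage
    guarantees this); T defaults to 298 K.
    """
    re = np.asarray(relative_energies, dtype=float)
    if re.size == 0:
        raise ValueError("empty relative-energy list")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if re.min() < -1e-9:
        raise ValueError(f"relative energies must be >= 0 (min is {re.min()})")
    x = np.exp(-re / (BOLTZMANN_KCAL * temperature))
    return BoltzmannWeights(re, temperature, x / x.sum())


def weighted_ccs(
    ccs_values,
    weights: BoltzmannWeights,
    population_window: float = POPULATION_WINDOW_KCAL,
) -> float:
    """Population-weighted CCS over conformers with RE <= window (inclusive),
    weights renormalized over that subset.  If only the global minimum is
    inside the window, its CCS is returned unchanged."""
    ccs = np.asarray(ccs_values, dtype=float)
    if ccs.shape != weights.populations.shape:
        raise ValueError(
            f"{ccs.size} CCS values for {weights.n} weights"
        )
    inside = weights.relative_energies <= population_window
    p = weights.populations[inside]
    return float((p / p.sum() * ccs[inside]).sum())


def percent_error(calc: float, ref: float) -> float:
    """|calc - ref| / ref * 100."""
    if ref <= 0:
        raise ValueError("reference CCS must be positive")
    return abs(calc - ref) / ref * 100.0


def percent_difference(a: float, b: float) -> float:
    """Symmetric discrepancy between two measurements:
    |a - b| / mean(a, b) * 100."""
    if a <= 0 or b <= 0:
        raise ValueError("both CCS values must be positive")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


# -- reference tables -----------------------------------------------------


def load_reference_table(name_or_path) -> pd.DataFrame:
    """Load a bundled table ("table1", "table2", "table3") or a user CSV.

    User tables need columns analyte, mode and at least one of
    single_A2 / stepped_A2; an avg_A2 column (arithmetic mean of the two
    when both exist) is derived when absent.  For bundled tables the
    number of printed decimals of calc_A2 is recorded in calc_decimals.
    """
    name = str(name_or_path)
    if name in ("table1", "table2", "table3"):
        source = resources.files("glyccs.data").joinpath(f"{name}.csv")
        text = source.read_text()
    else:
        text = Path(name_or_path).read_text()
    from io import StringIO

    df = pd.read_csv(StringIO(text), comment="#", dtype={"calc_A2": str})
    if "calc_A2" in df.columns:
        decs = df["calc_A2"].map(lambda s: len(s.split(".")[1]) if isinstance(s, str) and "." in s else 0)
        df["calc_decimals"] = decs
        df["calc_A2"] = df["calc_A2"].astype(float)
    if "avg_A2" not in df.columns and {"single_A2", "stepped_A2"} <= set(df.columns):
        df["avg_A2"] = df[["single_A2", "stepped_A2"]].mean(axis=1)
    missing_both = df.get("single_A2").isna() & df.get("stepped_A2").isna() if {
        "single_A2",
        "stepped_A2",
    } <= set(df.columns) else pd.Series(False, index=df.index)
    if missing_both.any():
        raise ValueError("reference rows must carry at least one experimental value")
    return df


def reference_errors(df: pd.DataFrame, policy: str = "averaged") -> pd.Series:
    """Percent error of each row's computed CCS against the policy-selected
    reference, recomputed from the CCS columns (not the printed errors)."""
    if policy not in _POLICIES:
        raise ValueError(f"unknown reference policy {policy!r} (have {_POLICIES})")
    calc = df["calc_A2"].astype(float)
    if policy == "averaged":
        ref = df[["single_A2", "stepped_A2"]].mean(axis=1)
        return (calc - ref).abs() / ref * 100.0
    if policy in ("single", "stepped"):
        ref = df[f"{policy}_A2"]
        return (calc - ref).abs() / ref * 100.0
    err_s = (calc - df["single_A2"]).abs() / df["single_A2"] * 100.0
    err_t = (calc - df["stepped_A2"]).abs() / df["stepped_A2"] * 100.0
    return pd.concat([err_s, err_t], axis=1).min(axis=1)


def success_rate(
    df: pd.DataFrame,
    threshold: float = SUCCESS_THRESHOLD_PCT,
    policy: str = "averaged",
) -> tuple[int, float]:
    """(count, fraction) of systems whose policy-selected CCS error is
    <= threshold.  ``best_of_methods`` takes, per system, whichever of the
    single- or stepped-field references agrees better."""
    if len(df) == 0:
        raise ValueError("empty assignment table")
    err = reference_errors(df, policy).dropna()
    if len(err) == 0:
        raise ValueError(f"no rows carry a reference under policy {policy!r}")
    count = int((err <= threshold).sum())
    return count, count / len(err)


def error_summary(df: pd.DataFrame, printed_style: bool = True) -> dict:
    """Mean +/- sd of percent errors per reference policy.

    With ``printed_style`` the means/sds are rounded to integers, matching
    the presentation convention of the reference tables' aggregate rows.
    """
    out = {}
    for policy in ("single", "stepped", "averaged"):
        err = reference_errors(df, policy).dropna()
        mean, sd = float(err.mean()), float(err.std(ddof=1))
        if printed_style:
            out[policy] = {"mean": int(_round_half_up(mean, 0)), "sd": int(_round_half_up(sd, 0)), "n": len(err)}
        else:
            out[policy] = {"mean": mean, "sd": sd, "n": len(err)}
    return out


def _round_half_up(x: float, decimals: int) -> float:
    factor = 10.0**decimals
    return np.floor(x * factor + 0.5) / factor


def table1_percent_differences(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stepped-vs-single %difference per analyte plus the grand mean,
    recomputed from the CCS columns of the method-comparison table."""
    if df is None:
        df = load_reference_table("table1")
    pct = [percent_difference(a, b) for a, b in zip(df["stepped_A2"], df["single_A2"])]
    out = df[["analyte", "mode"]].copy()
    out["pct_difference"] = pct
    return out


# -- assignment report ----------------------------------------------------


@dataclass
class AssignmentRow:
    system: str
    mode: str
    ccs_global_min: float
    ccs_weighted: float
    reference: float | None = None
    error_pct: float | None = None
    success: bool | None = None


@dataclass
class AssignmentReport:
    rows: list[AssignmentRow]
    threshold: float = SUCCESS_THRESHOLD_PCT
    policy: str = "averaged"
    metadata: dict = field(default_factory=dict)

    def finalize(self) -> None:
        for r in self.rows:
            if r.reference is not None:
                r.error_pct = percent_error(r.ccs_weighted, r.reference)
                r.success = r.error_pct <= self.threshold

    @property
    def n_success(self) -> int:
        return sum(1 for r in self.rows if r.success)

    def to_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold,
            "policy": self.policy,
            "metadata": self.metadata,
            "rows": [
                {
                    "system": r.system,
                    "mode": r.mode,
                    "ccs_global_min_A2": _r6(r.ccs_global_min),
                    "ccs_weighted_A2": _r6(r.ccs_weighted),
                    "reference_A2": _r6(r.reference),
                    "error_pct": _r6(r.error_pct),
                    "success": r.success,
                }
                for r in self.rows
            ],
            "n_success": self.n_success,
            "n_with_reference": sum(1 for r in self.rows if r.reference is not None),
        }


def _r6(x):
    return None if x is None else round(float(x), 6)


def isomer_ordering(ccs_by_id: dict, pairs: list[tuple]) -> pd.DataFrame:
    """Report expected CCS orderings between isomer pairs.

    ``ccs_by_id`` maps an isomer id to either a CCS value or a
    (CCS, uncertainty) tuple; ``pairs`` is a list of (a, b, relation) where
    relation is ">" or "<".  When the CCS difference is within the combined
    uncertainties the pair is reported as indistinguishable rather than
    pass/fail.
    """
    rows = []
    for a, b, relation in pairs:
        if relation not in (">", "<"):
            raise ValueError(f"relation must be '>' or '<', got {relation!r}")
        if a not in ccs_by_id or b not in ccs_by_id:
            rows.append({"a": a, "b": b, "expected": relation, "observed": None, "status": "incomparable"})
            continue
        va, ea = _unpack(ccs_by_id[a])
        vb, eb = _unpack(ccs_by_id[b])
        diff = va - vb
        if abs(diff) <= ea + eb:
            status = "indistinguishable"
            observed = "~"
        else:
            observed = ">" if diff > 0 else "<"
            status = "pass" if observed == relation else "fail"
        rows.append({"a": a, "b": b, "expected": relation, "observed": observed, "status": status})
    return pd.DataFrame(rows)


def _unpack(value) -> tuple[float, float]:
    if isinstance(value, (tuple, list)):
        return float(value[0]), float(value[1])
    return float(value), 0.0
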