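"""Arm-level trial data model, delimited-file I/O and evidence networks.

One row of the arm table is one randomized dosing arm of one trial,
carrying whichever outcomes the trial reported: baseline-to-endpoint
ADHD-RS-IV total-score change (mean and standard error), CGI-I response
counts, and all-cause / adverse-event-related discontinuation counts.
Trial-level design covariates (duration, mean age, percent female,
baseline ADHD-RS-IV) live in a companion trial table or, equivalently,
as repeated columns of a single joined wide file.

All doses of a drug are pooled to a single treatment node.  Plain "MPH"
arms that do not state the formulation are resolved by dosing frequency:
more than twice daily is treated as immediate release, otherwise
extended release.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Treatment",
    "Outcome",
    "ArmRecord",
    "TrialRecord",
    "TrialSet",
    "EvidenceNetwork",
    "ConnectivityReport",
    "ValidationError",
    "ParseError",
    "read_arm_table",
    "write_arm_table",
    "classify_mph",
    "apply_treatment_overrides",
    "filter_trials",
    "build_network",
    "check_connectivity",
    "center_covariates",
    "COVARIATE_NAMES",
]


class ValidationError(ValueError):
    """A record violates a data invariant (e.g. responders > n)."""


class ParseError(ValueError):
    """A cell in a delimited file could not be parsed; names row and column."""


class Treatment(str, Enum):
    """Pooled treatment nodes, in the fixed reporting order (placebo first)."""

    PLACEBO = "PLACEBO"
    GXR = "GXR"
    LDX = "LDX"
    ATX = "ATX"
    MPH_ER = "MPH_ER"
    MPH_IR = "MPH_IR"

    @property
    def order(self) -> int:
        return TREATMENT_ORDER.index(self)


TREATMENT_ORDER: tuple[Treatment, ...] = (
    Treatment.PLACEBO,
    Treatment.GXR,
    Treatment.LDX,
    Treatment.ATX,
    Treatment.MPH_ER,
    Treatment.MPH_IR,
)


class Outcome(str, Enum):
    ADHDRS_CHANGE = "ADHDRS_CHANGE"
    CGI_I = "CGI_I"
    DISC_ALL = "DISC_ALL"
    DISC_AE = "DISC_AE"

    @property
    def is_binary(self) -> bool:
        return self is not Outcome.ADHDRS_CHANGE

    @property
    def count_field(self) -> str | None:
        return {
            Outcome.CGI_I: "responders",
            Outcome.DISC_ALL: "dropouts_all",
            Outcome.DISC_AE: "dropouts_ae",
        }.get(self)

    @property
    def higher_is_better(self) -> bool:
        """Direction of a favourable effect on the modeled scale.

        Score change: more negative is better.  CGI-I response: higher is
        better.  Discontinuations: lower is better.
        """
        return self is Outcome.CGI_I


COVARIATE_NAMES = ("mean_age", "pct_female", "baseline_adhdrs")

SHORT_TERM_WEEKS = 3.0  # trials at or below this double-blind duration


def classify_mph(doses_per_day: int) -> Treatment:
    """Resolve an unlabelled methylphenidate arm by dosing frequency.

    Administration more than twice a day implies an immediate-release
    formulation; twice daily or less implies extended release / OROS.
    """
    if doses_per_day is None or doses_per_day < 1:
        raise ValidationError(f"doses_per_day must be a positive integer, got {doses_per_day!r}")
    return Treatment.MPH_IR if doses_per_day > 2 else Treatment.MPH_ER


@dataclass(frozen=True)
class ArmRecord:
    """One randomized arm: sample size plus the outcomes the trial reported."""

    trial_id: str
    treatment: Treatment
    n: int
    mean_change: float | None = None
    se_change: float | None = None
    responders: int | None = None
    dropouts_all: int | None = None
    dropouts_ae: int | None = None
    doses_per_day: int | None = None

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValidationError("arm with missing trial_id")
        if not isinstance(self.treatment, Treatment):
            raise ValidationError(f"unknown treatment label {self.treatment!r}")
        if self.n <= 0:
            raise ValidationError(f"{self.trial_id}: arm n must be positive, got {self.n}")
        for name in ("responders", "dropouts_all", "dropouts_ae"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= self.n:
                raise ValidationError(f"{self.trial_id}: {name}={v} outside [0, n={self.n}]")
        if (self.mean_change is None) != (self.se_change is None):
            raise ValidationError(f"{self.trial_id}: mean_change and se_change must come together")
        if self.se_change is not None and self.se_change <= 0:
            raise ValidationError(f"{self.trial_id}: se_change must be positive")
        if not any(
            getattr(self, f) is not None
            for f in ("mean_change", "responders", "dropouts_all", "dropouts_ae")
        ):
            raise ValidationError(f"{self.trial_id}: arm reports no outcome")

    def reports(self, outcome: Outcome) -> bool:
        if outcome is Outcome.ADHDRS_CHANGE:
            return self.mean_change is not None and self.se_change is not None
        return getattr(self, outcome.count_field) is not None

    def events(self, outcome: Outcome) -> int:
        assert outcome.is_binary
        v = getattr(self, outcome.count_field)
        if v is None:
            raise ValidationError(f"{self.trial_id}: no {outcome.value} count")
        return int(v)


@dataclass(frozen=True)
class TrialRecord:
    """Trial-level design metadata and meta-regression covariates."""

    trial_id: str
    duration_weeks: float
    mean_age: float | None = None
    pct_female: float | None = None
    baseline_adhdrs: float | None = None
    open_label: bool | None = None

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValidationError("trial with missing trial_id")
        if not 0 < self.duration_weeks <= 16:
            raise ValidationError(
                f"{self.trial_id}: duration_weeks must lie in (0, 16], got {self.duration_weeks}"
            )
        if self.pct_female is not None and not 0 <= self.pct_female <= 100:
            raise ValidationError(f"{self.trial_id}: pct_female outside [0, 100]")
        if self.baseline_adhdrs is not None and not 0 <= self.baseline_adhdrs <= 54:
            raise ValidationError(f"{self.trial_id}: baseline_adhdrs outside [0, 54]")

    @property
    def short_term(self) -> bool:
        return self.duration_weeks <= SHORT_TERM_WEEKS


@dataclass
class TrialSet:
    """A validated collection of trials with their arms."""

    trials: dict[str, TrialRecord]
    arms: list[ArmRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_trial: dict[str, list[ArmRecord]] = {}
        for arm in self.arms:
            if arm.trial_id not in self.trials:
                raise ValidationError(f"arm references unknown trial {arm.trial_id!r}")
            by_trial.setdefault(arm.trial_id, []).append(arm)
        for tid in self.trials:
            arms = by_trial.get(tid, [])
            if len({a.treatment for a in arms}) < 2:
                raise ValidationError(f"{tid}: trial needs >=2 arms with distinct treatments")

    def arms_of(self, trial_id: str) -> list[ArmRecord]:
        return [a for a in self.arms if a.trial_id == trial_id]

    @property
    def trial_ids(self) -> list[str]:
        return sorted(self.trials)

    def treatments(self) -> list[Treatment]:
        present = {a.treatment for a in self.arms}
        return [t for t in TREATMENT_ORDER if t in present]

    def total_n(self, trial_id: str) -> int:
        return sum(a.n for a in self.arms_of(trial_id))

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Arm and trial tables as DataFrames in canonical column/row order."""
        arm_rows = [
            {
                "trial_id": a.trial_id,
                "treatment": a.treatment.value,
                "n": a.n,
                "mean_change": a.mean_change,
                "se_change": a.se_change,
                "responders": a.responders,
                "dropouts_all": a.dropouts_all,
                "dropouts_ae": a.dropouts_ae,
                "doses_per_day": a.doses_per_day,
            }
            for a in sorted(self.arms, key=lambda a: (a.trial_id, a.treatment.order))
        ]
        trial_rows = [
            {
                "trial_id": t.trial_id,
                "duration_weeks": t.duration_weeks,
                "mean_age": t.mean_age,
                "pct_female": t.pct_female,
                "baseline_adhdrs": t.baseline_adhdrs,
                "open_label": t.open_label,
            }
            for t in (self.trials[tid] for tid in self.trial_ids)
        ]
        return pd.DataFrame(arm_rows), pd.DataFrame(trial_rows)

    def digest_text(self) -> str:
        """Canonical text serialization used for run-manifest digests."""
        arms_df, trials_df = self.to_frames()
        return arms_df.to_csv(index=False) + "\n" + trials_df.to_csv(index=False)


ARM_COLUMNS = (
    "trial_id",
    "treatment",
    "n",
    "mean_change",
    "se_change",
    "responders",
    "dropouts_all",
    "dropouts_ae",
    "doses_per_day",
)
TRIAL_COLUMNS = (
    "trial_id",
    "duration_weeks",
    "mean_age",
    "pct_female",
    "baseline_adhdrs",
    "open_label",
)

_INT_FIELDS = {"n", "responders", "dropouts_all", "dropouts_ae", "doses_per_day"}
_BOOL_FIELDS = {"open_label"}


def _cell(df: pd.DataFrame, row: int, col: str):
    """Parse one cell; empty -> None; malformed -> ParseError naming row/column."""
    raw = df.at[row, col] if col in df.columns else None
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in ("nan", "na", "none"):
        return None
    if col in _BOOL_FIELDS:
        if s.lower() in ("true", "1", "yes"):
            return True
        if s.lower() in ("false", "0", "no"):
            return False
        raise ParseError(f"row {row + 2}, column {col!r}: cannot parse boolean {s!r}")
    if col == "trial_id" or col == "treatment":
        return s
    try:
        v = float(s)
    except ValueError:
        raise ParseError(f"row {row + 2}, column {col!r}: cannot parse number {s!r}") from None
    if col in _INT_FIELDS:
        if v != int(v):
            raise ParseError(f"row {row + 2}, column {col!r}: expected integer, got {s!r}")
        return int(v)
    return v


def _resolve_treatment(label: str, doses_per_day: int | None, where: str) -> Treatment:
    norm = label.strip().upper().replace("-", "_").replace(" ", "_")
    aliases = {"PBO": "PLACEBO", "MPH_OROS": "MPH_ER", "MPH_ER/OROS": "MPH_ER"}
    norm = aliases.get(norm, norm)
    if norm == "MPH":
        if doses_per_day is None:
            raise ValidationError(
                f"{where}: raw MPH arm needs doses_per_day for ER/IR classification"
            )
        return classify_mph(doses_per_day)
    try:
        return Treatment(norm)
    except ValueError:
        raise ValidationError(f"{where}: unknown treatment label {label!r}") from None


def read_arm_table(
    path,
    trials_path=None,
    *,
    delimiter: str = ",",
) -> TrialSet:
    """Read arm-level trial data from delimited text.

    Either a pair of files (arm table plus trial table) or a single joined
    wide file in which the trial-level columns are repeated on every arm
    row; repeated values must agree within a trial.  Unknown columns are
    ignored.  Rows with a missing trial_id are rejected.
    """
    arms_df = pd.read_csv(path, sep=delimiter, dtype=str)
    if "trial_id" not in arms_df.columns or "treatment" not in arms_df.columns:
        raise ParseError("arm table must have trial_id and treatment columns")

    if trials_path is not None:
        trials_df = pd.read_csv(trials_path, sep=delimiter, dtype=str)
    else:
        if "duration_weeks" not in arms_df.columns:
            raise ParseError("joined wide file must carry duration_weeks on every row")
        trials_df = None

    arms: list[ArmRecord] = []
    trial_meta: dict[str, dict] = {}
    for i in range(len(arms_df)):
        tid = _cell(arms_df, i, "trial_id")
        if tid is None:
            raise ValidationError(f"row {i + 2}: missing trial_id")
        fields = {c: _cell(arms_df, i, c) for c in ARM_COLUMNS if c not in ("trial_id", "treatment")}
        label = _cell(arms_df, i, "treatment")
        if label is None:
            raise ValidationError(f"row {i + 2}: missing treatment")
        treatment = _resolve_treatment(label, fields.get("doses_per_day"), f"row {i + 2}")
        if fields.get("n") is None:
            raise ValidationError(f"row {i + 2}: missing n")
        arms.append(ArmRecord(trial_id=tid, treatment=treatment, **fields))
        if trials_df is None:
            meta = {c: _cell(arms_df, i, c) for c in TRIAL_COLUMNS if c != "trial_id"}
            prev = trial_meta.setdefault(tid, meta)
            if prev != meta:
                raise ValidationError(f"{tid}: trial-level columns disagree across arm rows")

    trials: dict[str, TrialRecord] = {}
    if trials_df is not None:
        for i in range(len(trials_df)):
            tid = _cell(trials_df, i, "trial_id")
            if tid is None:
                raise ValidationError(f"trial table row {i + 2}: missing trial_id")
            meta = {c: _cell(trials_df, i, c) for c in TRIAL_COLUMNS if c != "trial_id"}
            if meta.get("duration_weeks") is None:
                raise ValidationError(f"{tid}: missing duration_weeks")
            trials[tid] = TrialRecord(trial_id=tid, **meta)
    else:
        for tid, meta in trial_meta.items():
            if meta.get("duration_weeks") is None:
                raise ValidationError(f"{tid}: missing duration_weeks")
            trials[tid] = TrialRecord(trial_id=tid, **meta)

    return TrialSet(trials=trials, arms=arms)


def write_arm_table(ts: TrialSet, path, trials_path=None, *, delimiter: str = ",") -> None:
    """Write a TrialSet back to delimited text (inverse of read_arm_table)."""
    arms_df, trials_df = ts.to_frames()
    if trials_path is not None:
        arms_df.to_csv(path, sep=delimiter, index=False)
        trials_df.to_csv(trials_path, sep=delimiter, index=False)
    else:
        wide = arms_df.merge(trials_df, on="trial_id", how="left")
        wide.to_csv(path, sep=delimiter, index=False)


def apply_treatment_overrides(ts: TrialSet, overrides: Mapping[str, Treatment | str]) -> TrialSet:
    """Force the drug label of specific trials (trial_id -> new label).

    Applies to every methylphenidate arm of the named trial; this supports
    the ER/IR reclassification sensitivity for trials whose formulation was
    imputed from dosing frequency.
    """
    new_arms = []
    for arm in ts.arms:
        if arm.trial_id in overrides and arm.treatment in (Treatment.MPH_ER, Treatment.MPH_IR):
            target = overrides[arm.trial_id]
            target = Treatment(target) if not isinstance(target, Treatment) else target
            new_arms.append(replace(arm, treatment=target))
        else:
            new_arms.append(arm)
    return TrialSet(trials=dict(ts.trials), arms=new_arms)


def _pool_arms(arms: Sequence[ArmRecord]) -> ArmRecord:
    """Combine same-treatment dose arms: counts summed, means IV-weighted."""
    if len(arms) == 1:
        return arms[0]
    n = sum(a.n for a in arms)

    def sum_counts(field: str):
        vals = [getattr(a, field) for a in arms]
        return None if any(v is None for v in vals) else sum(vals)

    mean = se = None
    if all(a.mean_change is not None for a in arms):
        w = np.array([1.0 / a.se_change**2 for a in arms])
        m = np.array([a.mean_change for a in arms])
        mean = float(np.sum(w * m) / np.sum(w))
        se = float(1.0 / math.sqrt(np.sum(w)))
    return ArmRecord(
        trial_id=arms[0].trial_id,
        treatment=arms[0].treatment,
        n=n,
        mean_change=mean,
        se_change=se,
        responders=sum_counts("responders"),
        dropouts_all=sum_counts("dropouts_all"),
        dropouts_ae=sum_counts("dropouts_ae"),
    )


def filter_trials(
    ts: TrialSet,
    outcome: Outcome,
    exclude_short_term: bool = True,
    required_covariates: Sequence[str] = (),
) -> TrialSet:
    """Restrict a TrialSet to the analysis set for one outcome.

    Keeps trials with at least two distinct-treatment arms reporting the
    outcome (only those arms are retained, and same-treatment dose arms are
    pooled to one arm per drug); drops short-term trials (duration <= 3
    weeks) when requested; drops trials missing any required meta-regression
    covariate.
    """
    for cov in required_covariates:
        if cov not in COVARIATE_NAMES:
            raise ValueError(f"unknown covariate {cov!r}")
    trials: dict[str, TrialRecord] = {}
    arms: list[ArmRecord] = []
    for tid in ts.trial_ids:
        trial = ts.trials[tid]
        if exclude_short_term and trial.short_term:
            continue
        if any(getattr(trial, cov) is None for cov in required_covariates):
            continue
        reporting = [a for a in ts.arms_of(tid) if a.reports(outcome)]
        by_treat: dict[Treatment, list[ArmRecord]] = {}
        for a in reporting:
            by_treat.setdefault(a.treatment, []).append(a)
        if len(by_treat) < 2:
            continue
        trials[tid] = trial
        for treat in TREATMENT_ORDER:
            if treat in by_treat:
                arms.append(_pool_arms(by_treat[treat]))
    if not trials:
        import warnings

        warnings.warn(f"no trials left for {outcome.value} after filtering", stacklevel=2)
    return TrialSet(trials=trials, arms=arms)


@dataclass(frozen=True)
class EvidenceNetwork:
    """Treatments as nodes, trials as multi-edges, for one outcome."""

    nodes: tuple[Treatment, ...]
    edges: tuple[tuple[Treatment, Treatment, str], ...]
    outcome: Outcome

    def edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.value, b.value, tid) for a, b, tid in self.edges],
            columns=["treatment_a", "treatment_b", "trial_id"],
        )

    def to_json_summary(self) -> str:
        adj: dict[str, dict[str, int]] = {t.value: {} for t in self.nodes}
        for a, b, _ in self.edges:
            adj[a.value][b.value] = adj[a.value].get(b.value, 0) + 1
            adj[b.value][a.value] = adj[b.value].get(a.value, 0) + 1
        return json.dumps(
            {
                "outcome": self.outcome.value,
                "nodes": [t.value for t in self.nodes],
                "adjacency": adj,
            },
            sort_keys=True,
        )


def build_network(ts: TrialSet, outcome: Outcome) -> EvidenceNetwork:
    """Build the evidence network from an already-filtered TrialSet.

    Every trial with a arms contributes C(a, 2) edges.  Node order is the
    fixed treatment order with placebo first.
    """
    edges: list[tuple[Treatment, Treatment, str]] = []
    present: set[Treatment] = set()
    for tid in ts.trial_ids:
        arms = sorted(ts.arms_of(tid), key=lambda a: a.treatment.order)
        present.update(a.treatment for a in arms)
        for i in range(len(arms)):
            for j in range(i + 1, len(arms)):
                edges.append((arms[i].treatment, arms[j].treatment, tid))
    nodes = tuple(t for t in TREATMENT_ORDER if t in present)
    return EvidenceNetwork(nodes=nodes, edges=tuple(edges), outcome=outcome)


@dataclass(frozen=True)
class ConnectivityReport:
    connected: bool
    components: tuple[tuple[Treatment, ...], ...]
    missing_anchors: tuple[Treatment, ...]


def check_connectivity(
    net: EvidenceNetwork, anchors: Sequence[Treatment] = ()
) -> ConnectivityReport:
    """Check that all nodes and anchor treatments sit in one component.

    A treatment can only be compared if it is joined to the rest of the
    network through a chain of common comparators.
    """
    if not net.nodes:
        raise ValidationError("empty evidence network")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_edges_from((a, b) for a, b, _ in net.edges)
    comps = [
        tuple(sorted(c, key=lambda t: t.order)) for c in nx.connected_components(g)
    ]
    comps.sort(key=lambda c: c[0].order)
    missing = tuple(t for t in anchors if t not in net.nodes)
    connected = len(comps) == 1 and not missing
    return ConnectivityReport(connected=connected, components=tuple(comps), missing_anchors=missing)


def center_covariates(
    ts: TrialSet, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Center trial covariates at their sample-size-weighted grand means.

    Each trial is weighted by the total number of randomized patients in
    its included arms.  The returned table has one row per trial with the
    centered values; the grand means are reported alongside.
    """
    tids = ts.trial_ids
    weights = np.array([ts.total_n(tid) for tid in tids], dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("zero total weight when centering covariates")
    centered = pd.DataFrame(index=pd.Index(tids, name="trial_id"))
    grand_means: dict[str, float] = {}
    for cov in covariates:
        vals = []
        for tid in tids:
            v = getattr(ts.trials[tid], cov)
            if v is None:
                raise ValidationError(f"{tid}: covariate {cov} missing (filter first)")
            vals.append(float(v))
        vals = np.array(vals)
        gm = float(np.sum(weights * vals) / np.sum(weights))
        grand_means[cov] = gm
        centered[cov] = vals - gm
    return centered, grand_means
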