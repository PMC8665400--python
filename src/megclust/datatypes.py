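"""Core domain containers shared by every analysis stage.

The study design these types serve: a two-arm pre/post intervention cohort
(one row per participant, with the Conners CPT-III commission score as the
main inhibitory-control outcome) alongside source-reconstructed resting-state
MEG power, stored as a participants x nodes x frequency-steps tensor per
session. Everything downstream — post/pre ratios, node x frequency partial
correlation maps, spatio-spectral clusters and their permutation inference —
is expressed in terms of these containers.

Conventions: node indices and frequency-step indices are 0-based throughout;
physical frequencies (Hz) live only in ``freq_axis``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

ARMS = ("experimental", "control")
SEXES = ("M", "F")
SESSIONS = ("pre", "post")

#: columns every cohort table must provide
REQUIRED_COHORT_COLUMNS = (
    "participant_id",
    "arm",
    "age",
    "sex",
    "medicated",
    "psych_treatment",
    "cpt_commission_pre",
    "cpt_commission_post",
)

_FREQ_UNIFORM_TOL = 1e-9


class CohortError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass
class CohortTable:
    """One row per participant: demographics, arm, pre/post outcome scores.

    Parameters
    ----------
    data : pandas.DataFrame
        Must carry :data:`REQUIRED_COHORT_COLUMNS`; any additional columns are
        kept and treated as optional secondary outcomes.
    age_range : tuple of float
        Permitted (inclusive) age interval in years.
    """

    data: pd.DataFrame
    age_range: tuple[float, float] = (8.0, 11.0)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"cohort table missing required columns: {missing}")
        if len(df) == 0:
            raise CohortError("no participants in cohort table")
        ids = df["participant_id"].astype(str)
        dup = ids[ids.duplicated()].unique()
        if len(dup):
            raise CohortError(f"duplicate participant id(s): {list(dup)}")
        bad_arm = sorted(set(df["arm"]) - set(ARMS))
        if bad_arm:
            raise CohortError(f"unknown arm label(s): {bad_arm}; expected {ARMS}")
        for arm in ARMS:
            if not (df["arm"] == arm).any():
                raise CohortError(f"arm {arm!r} has no participants")
        ages = np.asarray(df["age"], float)
        lo, hi = self.age_range
        if not np.all(np.isfinite(ages)):
            raise CohortError("non-finite ages")
        if ages.min() < lo or ages.max() > hi:
            raise CohortError(
                f"ages outside configured range [{lo}, {hi}]: "
                f"min={ages.min()}, max={ages.max()}"
            )
        for col in ("cpt_commission_pre", "cpt_commission_post"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), "participant_id"].tolist()
                raise CohortError(f"non-numeric {col} for participant(s) {bad}")
            if not np.all(np.isfinite(vals)):
                raise CohortError(f"non-finite {col}")
        self.data = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def participant_ids(self) -> list[str]:
        return self.data["participant_id"].astype(str).tolist()

    @property
    def n(self) -> int:
        return len(self.data)

    def arm_mask(self, arm: str) -> np.ndarray:
        if arm not in ARMS:
            raise CohortError(f"unknown arm {arm!r}")
        return (self.data["arm"] == arm).to_numpy()

    @property
    def n_experimental(self) -> int:
        return int(self.arm_mask("experimental").sum())

    @property
    def n_control(self) -> int:
        return int(self.arm_mask("control").sum())

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.data["age"], float)

    def secondary_outcome_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_COHORT_COLUMNS]


def _check_freq_axis(freq_axis: np.ndarray) -> np.ndarray:
    freq_axis = np.asarray(freq_axis, float)
    if freq_axis.ndim != 1 or freq_axis.size < 2:
        raise ValueError("freq_axis must be a 1-d array with >= 2 steps")
    d = np.diff(freq_axis)
    if np.any(d <= 0):
        raise ValueError("freq_axis must be strictly increasing")
    if np.max(np.abs(d - d[0])) > max(_FREQ_UNIFORM_TOL, 1e-6 * abs(d[0])):
        raise ValueError(
            "non-uniform spacing in freq_axis "
            f"(steps range from {d.min():g} to {d.max():g} Hz)"
        )
    return freq_axis


@dataclass
class PowerTensor:
    """Participants x nodes x frequency-steps source-space power for one session."""

    values: np.ndarray
    freq_axis: np.ndarray
    session: str
    participant_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("power tensor must be 3-d (participants, nodes, steps)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite power values")
        if np.any(self.values < 0):
            raise ValueError("negative power values")
        self.freq_axis = _check_freq_axis(self.freq_axis)
        if self.values.shape[2] != self.freq_axis.size:
            raise ValueError(
                f"tensor has {self.values.shape[2]} frequency steps but "
                f"freq_axis has {self.freq_axis.size}"
            )
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        self.participant_order = [str(p) for p in self.participant_order]
        if len(self.participant_order) != self.values.shape[0]:
            raise ValueError("participant_order length does not match tensor")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_steps(self) -> int:
        return self.values.shape[2]

    def to_relative(self) -> "PowerTensor":
        """Per-node relative power: each spectrum normalised to unit sum.

        Offered because resting-state literature often analyses relative
        rather than absolute band power; the default pipeline uses absolute
        power.
        """
        totals = self.values.sum(axis=2, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError("cannot normalise: zero total power for some node")
        return PowerTensor(
            self.values / totals, self.freq_axis, self.session,
            list(self.participant_order),
        )


@dataclass
class RatioTensor:
    """Elementwise post/pre power ratio, same layout as :class:`PowerTensor`."""

    values: np.ndarray
    freq_axis: np.ndarray
    participant_order: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise ValueError("ratio tensor must be 3-d")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("non-finite ratio values")
        self.freq_axis = _check_freq_axis(self.freq_axis)
        if self.values.shape[2] != self.freq_axis.size:
            raise ValueError("freq_axis length mismatch")
        self.participant_order = [str(p) for p in self.participant_order]

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_steps(self) -> int:
        return self.values.shape[2]


@dataclass
class SourceGraph:
    """Source-node geometry: coordinates, spatial adjacency, optional ROI labels.

    ``edges`` is canonicalised to an (E, 2) integer array with a < b and no
    duplicates; adjacency is undirected by construction.
    """

    coords: np.ndarray
    edges: np.ndarray
    roi_labels: np.ndarray | None = None  # array of str, "unassigned" allowed
    spacing: float | None = None  # grid spacing in mm, when known

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_nodes, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = self.coords.shape[0]
        e = np.asarray(self.edges, int)
        if e.size == 0:
            e = np.empty((0, 2), int)
        if e.ndim != 2 or e.shape[1] != 2:
            raise ValueError("edges must be (E, 2)")
        if np.any(e < 0) or np.any(e >= n):
            raise ValueError("edge endpoint out of range")
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-edges are not allowed")
        e = np.sort(e, axis=1)
        self.edges = np.unique(e, axis=0)
        if self.roi_labels is not None:
            labels = np.asarray(self.roi_labels, dtype=object)
            if labels.shape != (n,):
                raise ValueError("roi_labels must have one entry per node")
            if any(str(x) == "" for x in labels):
                raise ValueError("empty ROI name")
            self.roi_labels = labels

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def has_edge(self, a: int, b: int) -> bool:
        a, b = (a, b) if a < b else (b, a)
        return bool(np.any((self.edges[:, 0] == a) & (self.edges[:, 1] == b)))


@dataclass
class CorrelationMap:
    """Node x frequency-step maps of age-partialed Spearman rho and p.

    ``valid`` marks cells where the correlation is defined (non-constant data
    after ranking and residualisation); invalid cells carry rho=0, p=1.
    """

    rho: np.ndarray
    pval: np.ndarray
    valid: np.ndarray
    covariate_name: str = "age"

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, float)
        self.pval = np.asarray(self.pval, float)
        self.valid = np.asarray(self.valid, bool)
        if not (self.rho.shape == self.pval.shape == self.valid.shape):
            raise ValueError("rho/pval/valid shape mismatch")
        if np.any(np.abs(self.rho) > 1 + 1e-12):
            raise ValueError("|rho| > 1")
        if np.any((self.pval < 0) | (self.pval > 1)):
            raise ValueError("p-values outside [0, 1]")

    @property
    def all_valid(self) -> bool:
        return bool(self.valid.all())


@dataclass(frozen=True)
class Cluster:
    """A sign-consistent spatio-spectrally connected set of (node, step) cells.

    ``mass`` is the sum of member Spearman rho values — since all members
    share the sign, |mass| equals the summed |rho|.
    """

    members: frozenset[tuple[int, int]]
    sign: int
    mass: float
    freq_span: tuple[int, int]
    extent_per_step: tuple[int, ...]  # node counts for each step in freq_span

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not self.members:
            raise ValueError("empty cluster")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def nodes(self) -> frozenset[int]:
        return frozenset(n for n, _ in self.members)

    @property
    def peak_extent_step(self) -> int:
        """Step index (absolute) with the largest node extent."""
        off = int(np.argmax(self.extent_per_step))
        return self.freq_span[0] + off


@dataclass
class ClusterInference:
    """Observed clusters plus their max-statistic permutation null."""

    clusters: list[Cluster]
    null_max_mass: np.ndarray
    p_values: np.ndarray
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        self.null_max_mass = np.asarray(self.null_max_mass, float)
        self.p_values = np.asarray(self.p_values, float)
        if self.null_max_mass.size != self.n_permutations:
            raise ValueError("null distribution length != n_permutations")
        if len(self.p_values) != len(self.clusters):
            raise ValueError("one p-value per cluster required")
        if np.any((self.p_values <= 0) | (self.p_values > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    def significant(self, alpha: float = 0.05) -> list[tuple[Cluster, float]]:
        return [
            (c, float(p))
            for c, p in zip(self.clusters, self.p_values)
            if p <= alpha
        ]


@dataclass
class ClusterParams:
    """Tuning parameters of the cluster-forming and permutation procedure.

    Defaults follow the analysis they implement: per-cell significance at
    alpha_node=.05, persistence over >= 4 consecutive frequency steps (a 1-Hz
    interval at 1/3-Hz resolution), a per-step spatial extent of at least 1%
    of all nodes, and 5000 permutations of the behavioural scores.
    """

    alpha_node: float = 0.05
    min_consecutive_steps: int = 4
    min_extent_fraction: float = 0.01
    n_permutations: int = 5000
    seed: int | None = None
    #: "node_runs": per-node persistence filter before component finding;
    #: "cluster_span": require the assembled cluster to span >= the minimum
    #: number of steps instead.
    persistence_mode: str = "node_runs"
    #: permute the behavioural ratio only (age stays with the power data), or
    #: "joint" to shuffle (behaviour, age) together.
    shuffle: str = "cpt_only"
    #: how the per-step extent criterion is enforced: "trim" removes the
    #: offending frequency steps from a component (re-forming components until
    #: stable), "discard" drops any component with a sub-threshold step.
    extent_mode: str = "trim"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_node < 1:
            raise ValueError("alpha_node must be in (0, 1)")
        if self.min_consecutive_steps < 1:
            raise ValueError("min_consecutive_steps must be >= 1")
        if not 0 <= self.min_extent_fraction < 1:
            raise ValueError("min_extent_fraction must be in [0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.persistence_mode not in ("node_runs", "cluster_span"):
            raise ValueError("persistence_mode must be 'node_runs' or 'cluster_span'")
        if self.shuffle not in ("cpt_only", "joint"):
            raise ValueError("shuffle must be 'cpt_only' or 'joint'")
        if self.extent_mode not in ("trim", "discard"):
            raise ValueError("extent_mode must be 'trim' or 'discard'")

    def min_extent_nodes(self, n_nodes: int) -> int:
        return int(np.ceil(self.min_extent_fraction * n_nodes))


def roi_label_map(graph: SourceGraph) -> Mapping[str, np.ndarray]:
    """ROI name -> array of node indices, skipping unassigned nodes."""
    if graph.roi_labels is None:
        raise ValueError("graph carries no ROI labels")
    out: dict[str, list[int]] = {}
    for i, name in enumerate(graph.roi_labels):
        name = str(name)
        if name == "unassigned":
            continue
        out.setdefault(name, []).append(i)
    return {k: np.asarray(v, int) for k, v in out.items()}
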