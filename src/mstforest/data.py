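"""Long-format multistate event-history data: domain types, I/O and risk-set extraction.

A multistate process over a finite state space S = {1, ..., N} is observed as a
chain of sojourns: each subject contributes one row per visited state, recording
when the state was entered, when (and how) it was left, and the covariates.
Censoring is encoded as an exit to state 0 with status 0, so a subject's state
is reconstructible at any time while under observation and unknown afterwards.

Each transition (h, j) is modelled on its own risk set (the "separate approach"):
subjects who exit h towards some other state j' are treated as censored for the
h -> j hazard. Two time scales are supported per transition: the study clock
("forward", time since entry into the initial state) and the sojourn clock
("reset", time since entry into h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: exit code used in files and in-memory tables for censored sojourns
CENSORED = 0

#: returned by :func:`state_at` once a censored subject is no longer observable
UNKNOWN = 0

#: name of the covariate injected by sojourn augmentation (entry time into the
#: origin state on the study clock, the "d" of a semi-Markov analysis)
ENTRY_TIME_COVARIATE = "entry_time"

CLOCK_FORWARD = "forward"
CLOCK_RESET = "reset"

_RESERVED_COLUMNS = ("id", "from", "to", "entry", "exit", "status")


class StructureError(ValueError):
    """Raised for an inconsistent transition-structure declaration."""


class DataError(ValueError):
    """Raised for invalid event-history tables, with row-level diagnostics."""


@dataclass(frozen=True)
class TransitionStructure:
    """Directed graph of allowed state transitions plus a clock per transition.

    Parameters
    ----------
    states
        Ordered state labels; the first is the initial state every subject
        occupies at time 0.
    transitions
        Allowed ordered pairs (h, j), h != j.
    clocks
        Mapping (h, j) -> "forward" | "reset". Defaults to "forward" for
        every transition.
    """

    states: tuple[int, ...]
    transitions: tuple[tuple[int, int], ...]
    clocks: Mapping[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        states = tuple(int(s) for s in self.states)
        transitions = tuple((int(h), int(j)) for h, j in self.transitions)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transitions", transitions)
        if len(set(states)) != len(states) or not states:
            raise StructureError("states must be a non-empty set of distinct labels")
        if CENSORED in states:
            raise StructureError(f"state label {CENSORED} is reserved for censoring")
        seen = set()
        for h, j in transitions:
            if h == j:
                raise StructureError(f"self-transition ({h}, {j}) not allowed")
            if h not in states or j not in states:
                raise StructureError(f"transition ({h}, {j}) uses unknown state")
            if (h, j) in seen:
                raise StructureError(f"duplicate transition ({h}, {j})")
            seen.add((h, j))
        clocks = dict(self.clocks)
        for tr, clock in clocks.items():
            tr = (int(tr[0]), int(tr[1]))
            if tr not in seen:
                raise StructureError(f"clock declared for unknown transition {tr}")
            if clock not in (CLOCK_FORWARD, CLOCK_RESET):
                raise StructureError(f"unknown clock {clock!r} for transition {tr}")
            if clock == CLOCK_RESET and tr[0] == states[0]:
                raise StructureError(
                    f"clock=reset on transition {tr} out of the initial state is "
                    "redundant (subjects enter the initial state at time 0); "
                    "declare it forward"
                )
        full = {tr: clocks.get(tr, CLOCK_FORWARD) for tr in transitions}
        object.__setattr__(self, "clocks", full)

    # -- derived views ---------------------------------------------------
    @property
    def initial(self) -> int:
        return self.states[0]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def absorbing(self) -> frozenset[int]:
        origins = {h for h, _ in self.transitions}
        return frozenset(s for s in self.states if s not in origins)

    def out_transitions(self, h: int) -> tuple[tuple[int, int], ...]:
        return tuple(tr for tr in self.transitions if tr[0] == h)

    def clock(self, transition: tuple[int, int]) -> str:
        return self.clocks[tuple(transition)]

    def state_index(self, state: int) -> int:
        return self.states.index(state)

    # -- constructors ----------------------------------------------------
    @classmethod
    def progressive(cls, n_states: int, clocks: Mapping | None = None) -> "TransitionStructure":
        """Chain 1 -> 2 -> ... -> n with no skips or returns."""
        if n_states < 2:
            raise StructureError("a progressive structure needs at least 2 states")
        states = tuple(range(1, n_states + 1))
        transitions = tuple((k, k + 1) for k in states[:-1])
        return cls(states, transitions, clocks or {})

    @classmethod
    def illness_death(cls, clocks: Mapping | None = None) -> "TransitionStructure":
        """Three-state structure healthy(1) -> ill(2), healthy(1) -> dead(3), ill(2) -> dead(3)."""
        return cls((1, 2, 3), ((1, 2), (1, 3), (2, 3)), clocks or {})

    def to_dict(self) -> dict:
        return {
            "states": list(self.states),
            "transitions": [list(t) for t in self.transitions],
            "clocks": {f"{h}->{j}": c for (h, j), c in self.clocks.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransitionStructure":
        clocks = {}
        for key, c in d.get("clocks", {}).items():
            h, j = key.split("->")
            clocks[(int(h), int(j))] = c
        return cls(
            tuple(d["states"]),
            tuple(tuple(t) for t in d["transitions"]),
            clocks,
        )


class MultistateDataset:
    """A validated long-format event-history table bound to a structure.

    One row per subject-sojourn with columns ``id, from, to, entry, exit,
    status`` followed by covariates. Rows of a subject chain: the exit
    time/state of one row is the entry time/state of the next; the final row
    either enters an absorbing state (status 1) or is censored (to = 0,
    status 0).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        structure: TransitionStructure,
        categorical: Sequence[str] | None = None,
    ):
        table = table.copy().reset_index(drop=True)
        missing = [c for c in _RESERVED_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"missing required columns: {missing}")
        self.structure = structure
        self.covariate_names: tuple[str, ...] = tuple(
            c for c in table.columns if c not in _RESERVED_COLUMNS
        )
        for col in ("from", "to", "status"):
            table[col] = table[col].astype(int)
        for col in ("entry", "exit"):
            table[col] = table[col].astype(float)
        table = table.sort_values(["id", "entry"], kind="stable").reset_index(drop=True)
        self.table = table
        if categorical is None:
            categorical = [
                c
                for c in self.covariate_names
                if table[c].dtype == object
                or isinstance(table[c].dtype, pd.CategoricalDtype)
                or table[c].dtype == bool
            ]
        self.categorical: tuple[str, ...] = tuple(categorical)
        unknown = set(self.categorical) - set(self.covariate_names)
        if unknown:
            raise DataError(f"categorical declaration names unknown covariates: {sorted(unknown)}")
        self._validate()
        self.tau = float(table["exit"].max()) if len(table) else 0.0

    # ------------------------------------------------------------------
    def _fail(self, rows: Iterable[int], message: str):
        rows = list(rows)
        raise DataError(f"{message} (rows {rows[:10]}{'...' if len(rows) > 10 else ''})")

    def _validate(self):
        t = self.table
        if len(t) == 0:
            return
        st = self.structure
        bad = t.index[~np.isfinite(t["entry"]) | ~np.isfinite(t["exit"])]
        if len(bad):
            self._fail(bad, "non-finite entry/exit times")
        bad = t.index[t["entry"] < 0]
        if len(bad):
            self._fail(bad, "negative entry times")
        bad = t.index[t["exit"] <= t["entry"]]
        if len(bad):
            self._fail(bad, "exit <= entry (zero-length sojourns are invalid)")
        bad = t.index[~t["from"].isin(st.states)]
        if len(bad):
            self._fail(bad, "unknown from-state")
        bad = t.index[t["from"].isin(st.absorbing)]
        if len(bad):
            self._fail(bad, "rows leaving an absorbing state")
        bad = t.index[~(t["to"].isin(st.states) | (t["to"] == CENSORED))]
        if len(bad):
            self._fail(bad, "unknown to-state")
        # status/to consistency
        bad = t.index[(t["status"] == 1) != (t["to"] != CENSORED)]
        if len(bad):
            self._fail(bad, "status=1 must coincide with a real to-state (censoring is to=0, status=0)")
        ev = t[t["status"] == 1]
        allowed = set(st.transitions)
        bad = ev.index[[(h, j) not in allowed for h, j in zip(ev["from"], ev["to"])]]
        if len(bad):
            self._fail(bad, "transition outside the declared structure")
        # per-subject chains
        for sid, g in t.groupby("id", sort=False):
            if g["from"].iloc[0] != st.initial or g["entry"].iloc[0] != 0.0:
                self._fail(g.index[:1], f"subject {sid!r} does not start in state {st.initial} at time 0")
            if len(g) > 1:
                prev, nxt = g.iloc[:-1], g.iloc[1:]
                broken = (
                    (prev["exit"].to_numpy() != nxt["entry"].to_numpy())
                    | (prev["to"].to_numpy() != nxt["from"].to_numpy())
                    | (prev["status"].to_numpy() != 1)
                )
                if broken.any():
                    self._fail(nxt.index[broken], f"broken sojourn chain for subject {sid!r}")
            last = g.iloc[-1]
            if last["status"] == 1 and last["to"] not in st.absorbing:
                # chain legitimately ends at an observed transition into a
                # transient state only if follow-up stopped exactly there,
                # which the format encodes as a subsequent censored row.
                self._fail(g.index[-1:], f"subject {sid!r} chain ends with a transition into a transient state")

    # ------------------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["id"].unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, subject_ids) -> "MultistateDataset":
        mask = self.table["id"].isin(np.asarray(subject_ids))
        return MultistateDataset(self.table[mask], self.structure, self.categorical)

    def subject_chain(self, subject_id) -> pd.DataFrame:
        g = self.table[self.table["id"] == subject_id]
        if len(g) == 0:
            raise KeyError(f"unknown subject id {subject_id!r}")
        return g

    def state_at(self, subject_id, s: float) -> int:
        """State occupied at time ``s`` (piecewise-constant interpolation).

        Returns :data:`UNKNOWN` (0) once ``s`` exceeds the last contact of a
        censored subject; subjects observed to reach an absorbing state remain
        in it forever.
        """
        if s < 0:
            raise ValueError("s must be nonnegative")
        g = self.subject_chain(subject_id)
        entry = g["entry"].to_numpy()
        exit_ = g["exit"].to_numpy()
        idx = np.searchsorted(entry, s, side="right") - 1
        if idx < 0:  # s == 0 handled by first row entry 0
            idx = 0
        row = g.iloc[idx]
        if s < row["exit"]:
            return int(row["from"])
        last = g.iloc[-1]
        if last["status"] == 1 and int(last["to"]) in self.structure.absorbing:
            return int(last["to"])
        return UNKNOWN

    def subject_summary(self) -> pd.DataFrame:
        """Per-subject last-contact summary used by IPCW weighting.

        Columns: ``t_last`` (time of last observed transition or censoring),
        ``absorbed`` (reached an absorbing state), ``censored``.
        """
        rows = []
        for sid, g in self.table.groupby("id", sort=False):
            last = g.iloc[-1]
            absorbed = bool(last["status"] == 1 and int(last["to"]) in self.structure.absorbing)
            rows.append((sid, float(last["exit"]), absorbed, not absorbed))
        return pd.DataFrame(rows, columns=["id", "t_last", "absorbed", "censored"]).set_index("id")

    def baseline_covariates(self) -> pd.DataFrame:
        """First-row covariates per subject, indexed by subject id."""
        first = self.table.groupby("id", sort=False).head(1)
        return first.set_index("id")[list(self.covariate_names)]

    def __repr__(self):
        return (
            f"<MultistateDataset n_subjects={self.n_subjects} n_records={len(self.table)} "
            f"states={self.structure.states} tau={self.tau:g}>"
        )


def state_at(dataset: MultistateDataset, subject_id, s: float) -> int:
    """Module-level alias for :meth:`MultistateDataset.state_at`."""
    return dataset.state_at(subject_id, s)


# ----------------------------------------------------------------------
# transition-specific datasets (the separate approach)
# ----------------------------------------------------------------------
@dataclass
class TransitionDataset:
    """Single-transition risk set on that transition's clock.

    One row per subject ever at risk in the origin state h. ``status`` marks
    an observed h -> j move; exits towards any other state are cause-specific
    censorings with ``competing`` set, and last-contact exits are plain
    censorings. ``entry`` is the left-truncation time on the transition's
    clock (the state-entry time under the forward clock, zero under reset);
    ``entry_offset`` is always the study-clock entry time d into h.
    """

    transition: tuple[int, int]
    clock: str
    time: np.ndarray
    status: np.ndarray
    entry: np.ndarray
    entry_offset: np.ndarray
    competing: np.ndarray
    covariates: pd.DataFrame
    subject_ids: np.ndarray
    categorical: tuple[str, ...] = ()

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.entry = np.asarray(self.entry, dtype=float)
        self.entry_offset = np.asarray(self.entry_offset, dtype=float)
        self.competing = np.asarray(self.competing, dtype=bool)
        n = len(self.time)
        for arr in (self.status, self.entry, self.entry_offset, self.competing):
            if len(arr) != n:
                raise DataError("TransitionDataset arrays must share length")
        if len(self.covariates) != n:
            raise DataError("covariate frame length mismatch")
        if np.any(self.status[self.competing] == 1):
            raise DataError("a competing exit cannot be an event for this transition")
        if np.any(self.time <= self.entry):
            raise DataError("time on clock must exceed the truncation entry time")
        self.covariates = self.covariates.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    @property
    def tau(self) -> float:
        return float(self.time.max()) if self.n else 0.0

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.covariates.columns)

    def with_outcome(self, time: np.ndarray, status: np.ndarray) -> "TransitionDataset":
        """Copy with replaced (time, status) — used by imputation."""
        return TransitionDataset(
            self.transition,
            self.clock,
            np.asarray(time, dtype=float),
            np.asarray(status, dtype=int),
            self.entry.copy(),
            self.entry_offset.copy(),
            self.competing.copy(),
            self.covariates.copy(),
            self.subject_ids.copy(),
            self.categorical,
        )

    def take(self, idx) -> "TransitionDataset":
        idx = np.asarray(idx)
        return TransitionDataset(
            self.transition,
            self.clock,
            self.time[idx],
            self.status[idx],
            self.entry[idx],
            self.entry_offset[idx],
            self.competing[idx],
            self.covariates.iloc[idx],
            self.subject_ids[idx],
            self.categorical,
        )


def extract_transition_dataset(
    dataset: MultistateDataset,
    transition: tuple[int, int],
    augment_sojourn: bool = False,
) -> TransitionDataset:
    """Build the risk set for one transition under the separate approach.

    When ``augment_sojourn`` is true the covariates are extended with
    :data:`ENTRY_TIME_COVARIATE`, the study-clock entry time d into the origin
    state (identically 0 for the initial state, where augmentation is a no-op).
    """
    transition = (int(transition[0]), int(transition[1]))
    if transition not in dataset.structure.transitions:
        raise StructureError(f"transition {transition} not in structure")
    h, j = transition
    clock = dataset.structure.clock(transition)
    rows = dataset.table[dataset.table["from"] == h]
    status = ((rows["to"] == j) & (rows["status"] == 1)).to_numpy().astype(int)
    competing = ((rows["status"] == 1) & (rows["to"] != j)).to_numpy()
    d = rows["entry"].to_numpy(dtype=float)
    if clock == CLOCK_RESET:
        time = (rows["exit"] - rows["entry"]).to_numpy(dtype=float)
        entry = np.zeros(len(rows))
    else:
        time = rows["exit"].to_numpy(dtype=float)
        entry = d.copy()
    cov = rows[list(dataset.covariate_names)].copy()
    categorical = dataset.categorical
    if augment_sojourn and h != dataset.structure.initial:
        cov[ENTRY_TIME_COVARIATE] = d
    return TransitionDataset(
        transition,
        clock,
        time,
        status,
        entry,
        d,
        competing,
        cov,
        rows["id"].to_numpy(),
        categorical,
    )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_long_csv(
    path,
    structure: TransitionStructure,
    categorical: Sequence[str] | None = None,
) -> MultistateDataset:
    """Read a long-format multistate CSV (columns id, from, to, entry, exit, status, covariates)."""
    table = pd.read_csv(path)
    return MultistateDataset(table, structure, categorical)


def write_long_csv(dataset: MultistateDataset, path) -> None:
    dataset.table.to_csv(path, index=False)
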