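"""Sequence-dependent DNA deformation energy onto a protein-bound target
conformation.

The model is a multivariate two-substate (generally S-substate) harmonic model
over dinucleotide steps with nearest-neighbour substate coupling — a
multivariate Ising-type model.  Each step i with dinucleotide context c and
substate s contributes

    E_local(i, s) = 1/2 (x_i - x0_{c,s})^T K_{c,s} (x_i - x0_{c,s}) + offset_{c,s}

where x_i is the target's helical coordinate vector at step i (inter-base-pair
parameters such as twist/roll/slide, optionally augmented with intra-base-pair
parameters of the flanking base pairs), plus a coupling J(c_i, c_{i+1})[s_i,
s_{i+1}] between adjacent substates.  The minimum-energy substate path is found
exactly by transfer-matrix dynamic programming.  Energies are in kcal/mol,
coordinates in degrees/Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetConformation",
    "DeformationModel",
    "DeformationResult",
    "local_energy",
    "deformation_energy",
    "baseline_random",
    "compare_elements",
    "read_target_conformation",
    "write_target_conformation",
]

BASES = "ACGT"


@dataclass
class TargetConformation:
    """Per-step helical coordinates of the protein-bound target structure.

    ``step_coords`` is (N-1, d_step); optional ``bp_coords`` (N, d_bp) holds
    intra-base-pair parameters which are folded into each step vector as
    (step, left bp, right bp)."""

    step_coords: np.ndarray
    bp_coords: np.ndarray | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.step_coords = np.atleast_2d(np.asarray(self.step_coords, dtype=float))
        if self.bp_coords is not None:
            self.bp_coords = np.atleast_2d(np.asarray(self.bp_coords, dtype=float))
            if self.bp_coords.shape[0] != self.step_coords.shape[0] + 1:
                raise ValueError("bp_coords must have one more row than step_coords")

    @property
    def n_steps(self) -> int:
        return self.step_coords.shape[0]

    @property
    def seq_length(self) -> int:
        return self.n_steps + 1

    def step_vectors(self) -> np.ndarray:
        """(N-1, d) per-step vectors; d = d_step (+ 2 * d_bp when present)."""
        if self.bp_coords is None:
            return self.step_coords
        return np.hstack(
            [self.step_coords, self.bp_coords[:-1], self.bp_coords[1:]]
        )


@dataclass
class DeformationModel:
    """Per-context substate equilibria, stiffnesses, offsets, and couplings."""

    contexts: list[str]
    n_substates: int
    dim: int
    x0: dict[tuple[str, int], np.ndarray]
    stiffness: dict[tuple[str, int], np.ndarray]
    offset: dict[tuple[str, int], float]
    coupling: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_substates < 1:
            raise ValueError("need at least one substate")
        for key, K in self.stiffness.items():
            K = np.asarray(K, dtype=float)
            if K.shape != (self.dim, self.dim):
                raise ValueError(f"stiffness {key} has shape {K.shape}, want square {self.dim}")
            if not np.allclose(K, K.T, atol=1e-8):
                raise ValueError(f"stiffness {key} is not symmetric")
            self.stiffness[key] = K

    def coupling_matrix(self, ctx_a: str, ctx_b: str) -> np.ndarray:
        J = self.coupling.get((ctx_a, ctx_b))
        if J is None:
            return np.zeros((self.n_substates, self.n_substates))
        return np.asarray(J, dtype=float)

    # -- JSON round trip ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        obj = {
            "contexts": self.contexts,
            "n_substates": self.n_substates,
            "dim": self.dim,
            "x0": {f"{c}|{s}": v.tolist() for (c, s), v in self.x0.items()},
            "stiffness": {f"{c}|{s}": v.tolist() for (c, s), v in self.stiffness.items()},
            "offset": {f"{c}|{s}": v for (c, s), v in self.offset.items()},
            "coupling": {f"{a}|{b}": np.asarray(v).tolist() for (a, b), v in self.coupling.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "DeformationModel":
        obj = json.loads(Path(path).read_text())

        def unkey(d, cast):
            out = {}
            for k, v in d.items():
                a, b = k.split("|")
                out[(a, int(b) if b.isdigit() else b)] = cast(v)
            return out

        coupling = {}
        for k, v in obj["coupling"].items():
            a, b = k.split("|")
            coupling[(a, b)] = np.asarray(v, dtype=float)
        return cls(
            contexts=obj["contexts"],
            n_substates=obj["n_substates"],
            dim=obj["dim"],
            x0=unkey(obj["x0"], lambda v: np.asarray(v, dtype=float)),
            stiffness=unkey(obj["stiffness"], lambda v: np.asarray(v, dtype=float)),
            offset=unkey(obj["offset"], float),
            coupling=coupling,
        )


@dataclass
class DeformationResult:
    total_energy: float  # kcal/mol
    substate_path: list[int]
    local_energies: list[float]   # at the optimal path
    coupling_energies: list[float]  # between adjacent steps at the optimal path

    def check_decomposition(self) -> bool:
        return bool(
            np.isclose(
                self.total_energy,
                sum(self.local_energies) + sum(self.coupling_energies),
                atol=1e-8,
            )
        )


def local_energy(
    model: DeformationModel, context: str, substate: int, target_coords: np.ndarray
) -> float:
    """Harmonic substate energy 1/2 dx^T K dx + offset, kcal/mol."""
    key = (context, substate)
    if key not in model.x0:
        raise KeyError(f"unknown context/substate {key}")
    dx = np.asarray(target_coords, dtype=float) - model.x0[key]
    return float(0.5 * dx @ model.stiffness[key] @ dx + model.offset[key])


def deformation_energy(
    model: DeformationModel, seq: str, target: TargetConformation
) -> DeformationResult:
    """Minimum total deformation energy over all substate assignments.

    Computed exactly by transfer-matrix dynamic programming over the
    nearest-neighbour substate chain; returns the optimal path and its energy
    decomposition.
    """
    seq = seq.upper()
    if len(seq) != target.seq_length:
        raise ValueError(
            f"sequence length {len(seq)} != target length {target.seq_length}"
        )
    vectors = target.step_vectors()
    contexts = [seq[i : i + 2] for i in range(len(seq) - 1)]
    for c in contexts:
        if (c, 0) not in model.x0:
            raise KeyError(f"unknown context {c!r}")
    S = model.n_substates
    N = len(contexts)
    local = np.empty((N, S))
    for i, c in enumerate(contexts):
        for s in range(S):
            local[i, s] = local_energy(model, c, s, vectors[i])
    # transfer-matrix DP
    E = local[0].copy()
    back = np.zeros((N, S), dtype=int)
    for i in range(1, N):
        J = model.coupling_matrix(contexts[i - 1], contexts[i])
        tot = E[:, None] + J  # (prev substate, cur substate)
        back[i] = tot.argmin(axis=0)
        E = tot.min(axis=0) + local[i]
    s_last = int(E.argmin())
    path = [s_last]
    for i in range(N - 1, 0, -1):
        path.append(int(back[i][path[-1]]))
    path.reverse()
    locals_at = [float(local[i, path[i]]) for i in range(N)]
    couplings_at = [
        float(model.coupling_matrix(contexts[i], contexts[i + 1])[path[i], path[i + 1]])
        for i in range(N - 1)
    ]
    return DeformationResult(float(E[s_last]), path, locals_at, couplings_at)


def baseline_random(
    model: DeformationModel,
    target: TargetConformation,
    gc_fraction: float,
    n: int = 1000,
    seed: int = 0,
) -> tuple[float, float, float, np.ndarray]:
    """Deformation-energy baseline over i.i.d. random sequences of fixed GC.

    Returns (mean, sd, sem, energies)."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    L = target.seq_length
    energies = np.empty(n)
    for i in range(n):
        seq = "".join(BASES[j] for j in rng.choice(4, size=L, p=p))
        energies[i] = deformation_energy(model, seq, target).total_energy
    mean = float(energies.mean())
    sd = float(energies.std(ddof=1))
    return mean, sd, sd / np.sqrt(n), energies


def compare_elements(
    model: DeformationModel,
    target: TargetConformation,
    seq_sets: dict[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-set mean +/- sem deformation energy, ordered by mean, with pairwise
    differences of means."""
    rows = []
    means: dict[str, float] = {}
    for name, seqs in seq_sets.items():
        if not seqs:
            raise ValueError(f"set {name!r} is empty")
        e = np.array(
            [deformation_energy(model, s, target).total_energy for s in seqs]
        )
        sem = float(e.std(ddof=1) / np.sqrt(len(e))) if len(e) > 1 else float("nan")
        means[name] = float(e.mean())
        rows.append(dict(set=name, n=len(e), mean=float(e.mean()), sd=float(e.std(ddof=1)) if len(e) > 1 else float("nan"), sem=sem))
    df = pd.DataFrame(rows).sort_values("mean").reset_index(drop=True)
    for other in means:
        df[f"diff_vs_{other}"] = df["mean"] - means[other]
    return df


def read_target_conformation(path: str | Path) -> TargetConformation:
    """Read a target conformation TSV (position + coordinate columns).

    Columns named ``bp_*`` are intra-base-pair parameters; all other non-
    position columns are per-step parameters.  Step rows are N-1; when bp
    columns are present the file has N rows and the step columns of the last
    row are ignored (NaN allowed)."""
    df = pd.read_csv(path, sep="\t")
    pos_cols = [c for c in df.columns if c.lower() in ("position", "pos", "step")]
    df = df.drop(columns=pos_cols)
    bp_cols = [c for c in df.columns if c.startswith("bp_")]
    step_cols = [c for c in df.columns if c not in bp_cols]
    if bp_cols:
        bp = df[bp_cols].to_numpy(dtype=float)
        steps = df[step_cols].to_numpy(dtype=float)[:-1]
        return TargetConformation(steps, bp, source=str(path))
    return TargetConformation(df[step_cols].to_numpy(dtype=float), source=str(path))


def write_target_conformation(target: TargetConformation, path: str | Path) -> None:
    n = target.n_steps
    if target.bp_coords is not None:
        d_step = target.step_coords.shape[1]
        steps = np.vstack([target.step_coords, np.full((1, d_step), np.nan)])
        data = {"position": np.arange(n + 1)}
        for j in range(d_step):
            data[f"step_{j}"] = steps[:, j]
        for j in range(target.bp_coords.shape[1]):
            data[f"bp_{j}"] = target.bp_coords[:, j]
    else:
        data = {"position": np.arange(n)}
        for j in range(target.step_coords.shape[1]):
            data[f"step_{j}"] = target.step_coords[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
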