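"""File formats, run configuration and seed derivation.

Everything on disk is plain delimited text or YAML:

* trajectory tables — CSV with columns individual_id, treatment, day, x, y;
* posterior draws — long (tidy) CSV with columns stage, level, group,
  individual_id, parameter, iteration, value;
* truth ledgers for synthetic studies — long CSV with columns level,
  group, individual_id, parameter, value;
* rasters — ESRI ASCII grid (see :mod:`movemix.landscape`);
* run configuration — YAML.

Per-individual RNG streams are derived from one master seed by stable
hashing of the individual id, so results cannot depend on execution order.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import TREATMENTS, IndividualParams, Trajectory, TreatmentParams
from .stage1 import Stage1Results

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_draws",
    "read_draws",
    "stage1_to_frame",
    "stage1_from_frame",
    "stage2_to_frame",
    "stage2_from_frame",
    "write_truth_ledger",
    "read_truth_ledger",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "derive_seed",
]

DRAW_COLUMNS = ["stage", "level", "group", "individual_id", "parameter", "iteration", "value"]


def derive_seed(master_seed: int, label: str) -> int:
    """Stable sub-seed below 2^31, derived by hashing the label."""
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def config_hash(config: "RunConfig") -> str:
    """Short hash of the canonical YAML dump, for run logs."""
    text = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Trajectories


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": traj.individual_id,
                    "treatment": traj.treatment,
                    "day": traj.days,
                    "x": traj.positions[:, 0],
                    "y": traj.positions[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory table, validating treatments, day uniqueness and
    coordinates. Rows are grouped per individual and sorted by day; day
    gaps are preserved (they reduce likelihood-eligible terms)."""
    df = pd.read_csv(path, dtype={"individual_id": str, "treatment": str}, float_precision="round_trip")
    required = {"individual_id", "treatment", "day", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory file must have columns {sorted(required)}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # header + 1-based
            raise ValueError(f"non-numeric coordinate in column {col!r} at line {row}")
    unknown = set(df["treatment"]) - set(TREATMENTS)
    if unknown:
        raise ValueError(f"unknown treatment label(s): {sorted(unknown)}")
    dups = df.duplicated(subset=["individual_id", "day"])
    if dups.any():
        key = df.loc[dups.idxmax(), ["individual_id", "day"]].tolist()
        raise ValueError(f"duplicate (individual, day) entry: {key}")
    out = []
    for ind_id, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("day")
        treatments = grp["treatment"].unique()
        if len(treatments) > 1:
            raise ValueError(f"individual {ind_id!r} has multiple treatment labels")
        out.append(
            Trajectory(
                individual_id=str(ind_id),
                treatment=str(treatments[0]),
                days=grp["day"].to_numpy(dtype=int),
                positions=grp[["x", "y"]].to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Draws (long tidy format)


def write_draws(frame: pd.DataFrame, path) -> None:
    """Write a draw table in the long format, byte-stable given identical
    input (fixed column order and row ordering)."""
    if list(frame.columns) != DRAW_COLUMNS:
        frame = frame[DRAW_COLUMNS]
    frame = frame.sort_values(
        ["stage", "level", "group", "individual_id", "parameter", "iteration"],
        kind="mergesort",
    )
    frame.to_csv(path, index=False)


def read_draws(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "group": str}, float_precision="round_trip")
    if list(df.columns) != DRAW_COLUMNS:
        raise ValueError(
            f"draw file schema mismatch: expected columns {DRAW_COLUMNS}, got {list(df.columns)}"
        )
    return df


def stage1_to_frame(res: Stage1Results) -> pd.DataFrame:
    """Stage-1 samples in the long draw format (one individual)."""
    df = res.to_frame()
    df.insert(0, "stage", "stage1")
    df.insert(1, "level", "individual")
    df.insert(2, "group", res.treatment)
    df.insert(3, "individual_id", res.individual_id)
    flag = pd.DataFrame(
        {
            "stage": ["stage1"],
            "level": ["individual"],
            "group": [res.treatment],
            "individual_id": [res.individual_id],
            "parameter": ["encamped_only"],
            "iteration": [0],
            "value": [float(res.encamped_only)],
        }
    )
    return pd.concat([df, flag], ignore_index=True)[DRAW_COLUMNS]


def stage1_from_frame(df: pd.DataFrame) -> Stage1Results:
    """Rebuild first-stage samples from a long draw table (one individual)."""
    ids = df["individual_id"].unique()
    if len(ids) != 1:
        raise ValueError("expected draws for exactly one individual")
    flag_rows = df[df["parameter"] == "encamped_only"]
    encamped_only = bool(flag_rows["value"].iloc[0]) if len(flag_rows) else False
    df = df[df["parameter"] != "encamped_only"]
    wide = df.pivot(index="iteration", columns="parameter", values="value").sort_index()
    beta_cols = sorted(c for c in wide.columns if c.startswith("beta_"))
    n = len(wide)
    return Stage1Results(
        individual_id=str(ids[0]),
        treatment=str(df["group"].iloc[0]),
        beta=wide[beta_cols].to_numpy(),
        gamma=wide["gamma"].to_numpy(),
        theta=wide["theta"].to_numpy(),
        sigma1_sq=wide["sigma1_sq"].to_numpy(),
        z=np.zeros((0, 0), dtype=np.uint8),
        encamped_only=encamped_only,
        n_iter=n,
        seed=None,
    )


def stage2_to_frame(results) -> pd.DataFrame:
    """Hierarchical samples in the long draw format (all iterations,
    burn-in included; the burn-in count travels as a parameter row)."""
    frames = []
    iters = np.arange(1, results.n_iter + 1)
    for i, ind_id in enumerate(results.individual_ids):
        group = results.treatments_by_id[ind_id]
        cols = {
            "gamma": results.gamma[:, i],
            "theta": results.theta[:, i],
            "sigma1_sq": results.sigma1_sq[:, i],
        }
        for l in range(results.beta.shape[2]):
            cols[f"beta_{l}"] = results.beta[:, i, l]
        for name, vals in cols.items():
            frames.append(
                pd.DataFrame(
                    {
                        "stage": "stage2",
                        "level": "individual",
                        "group": group,
                        "individual_id": ind_id,
                        "parameter": name,
                        "iteration": iters,
                        "value": vals,
                    }
                )
            )
    for g in results.groups:
        cols = {}
        k = results.treatment_mu_beta[g].shape[1]
        for l in range(k):
            cols[f"mu_beta_{l}"] = results.treatment_mu_beta[g][:, l]
        for a in range(k):
            for b in range(a, k):
                cols[f"Sigma_beta_{a}_{b}"] = results.treatment_Sigma_beta[g][:, a, b]
        cols.update(results.treatment_scalars[g])
        for name, vals in cols.items():
            frames.append(
                pd.DataFrame(
                    {
                        "stage": "stage2",
                        "level": "treatment",
                        "group": g,
                        "individual_id": "",
                        "parameter": name,
                        "iteration": iters,
                        "value": vals,
                    }
                )
            )
    meta = pd.DataFrame(
        {
            "stage": ["stage2"],
            "level": ["meta"],
            "group": [""],
            "individual_id": [""],
            "parameter": ["burn_in"],
            "iteration": [0],
            "value": [float(results.burn_in)],
        }
    )
    frames.append(meta)
    return pd.concat(frames, ignore_index=True)[DRAW_COLUMNS]


def stage2_from_frame(df: pd.DataFrame):
    """Rebuild :class:`~movemix.stage2.HierarchicalResults` from a long
    draw table written by :func:`stage2_to_frame`."""
    from .stage2 import HierarchicalResults

    meta = df[(df["level"] == "meta") & (df["parameter"] == "burn_in")]
    burn_in = int(meta["value"].iloc[0]) if len(meta) else 0
    ind = df[df["level"] == "individual"]
    trt = df[df["level"] == "treatment"]

    individual_ids = sorted(ind["individual_id"].unique())
    treatments_by_id = {
        str(i): str(g)
        for i, g in ind.drop_duplicates("individual_id")[["individual_id", "group"]].values
    }
    groups = sorted(trt["group"].unique())
    n_iter = int(ind["iteration"].max())
    k = sum(p.startswith("beta_") for p in ind["parameter"].unique())

    def ind_matrix(param):
        wide = ind[ind["parameter"] == param].pivot(
            index="iteration", columns="individual_id", values="value"
        )
        return wide[individual_ids].sort_index().to_numpy()

    beta = np.stack([ind_matrix(f"beta_{l}") for l in range(k)], axis=2)
    mu_beta, Sigma_beta, scalars = {}, {}, {}
    for g in groups:
        sub = trt[trt["group"] == g]
        wide = sub.pivot(index="iteration", columns="parameter", values="value").sort_index()
        mu_beta[g] = wide[[f"mu_beta_{l}" for l in range(k)]].to_numpy()
        S = np.empty((n_iter, k, k))
        for a in range(k):
            for b in range(a, k):
                S[:, a, b] = S[:, b, a] = wide[f"Sigma_beta_{a}_{b}"].to_numpy()
        Sigma_beta[g] = S
        scalars[g] = {
            name: wide[name].to_numpy()
            for name in (
                "mu_logit_gamma", "var_logit_gamma", "mu_theta",
                "var_theta", "mu_log_sigma1", "var_log_sigma1",
            )
        }
    return HierarchicalResults(
        individual_ids=[str(i) for i in individual_ids],
        treatments_by_id=treatments_by_id,
        groups=[str(g) for g in groups],
        gamma=ind_matrix("gamma"),
        theta=ind_matrix("theta"),
        sigma1_sq=ind_matrix("sigma1_sq"),
        beta=beta,
        treatment_mu_beta=mu_beta,
        treatment_Sigma_beta=Sigma_beta,
        treatment_scalars=scalars,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=None,
        acceptance_rates={},
    )


# ---------------------------------------------------------------------------
# Truth ledgers for synthetic studies


def write_truth_ledger(dataset, path) -> None:
    rows = []
    for ind_id, p in sorted(dataset.individual_truth.items()):
        group = next(
            t.treatment for t in dataset.trajectories if t.individual_id == ind_id
        )
        vals = {f"beta_{i}": v for i, v in enumerate(p.beta)}
        vals.update(gamma=p.gamma, theta=p.theta, sigma1_sq=p.sigma1_sq)
        for name, v in vals.items():
            rows.append(
                {"level": "individual", "group": group, "individual_id": ind_id,
                 "parameter": name, "value": float(v)}
            )
    for group, tp in sorted(dataset.treatment_truth.items()):
        vals = {f"mu_beta_{i}": v for i, v in enumerate(tp.mu_beta)}
        k = len(tp.mu_beta)
        for a in range(k):
            for b in range(a, k):
                vals[f"Sigma_beta_{a}_{b}"] = tp.Sigma_beta[a, b]
        vals.update(
            mu_logit_gamma=tp.mu_logit_gamma,
            var_logit_gamma=tp.var_logit_gamma,
            mu_theta=tp.mu_theta,
            var_theta=tp.var_theta,
            mu_log_sigma1=tp.mu_log_sigma1,
            var_log_sigma1=tp.var_log_sigma1,
        )
        for name, v in vals.items():
            rows.append(
                {"level": "treatment", "group": group, "individual_id": "",
                 "parameter": name, "value": float(v)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_ledger(path) -> tuple[dict[str, IndividualParams], dict[str, TreatmentParams]]:
    df = pd.read_csv(path, dtype={"individual_id": str, "group": str}, keep_default_na=False, float_precision="round_trip")
    individual: dict[str, IndividualParams] = {}
    for ind_id, grp in df[df["level"] == "individual"].groupby("individual_id"):
        vals = dict(zip(grp["parameter"], grp["value"]))
        beta = np.array([vals[k] for k in sorted(vals) if k.startswith("beta_")])
        individual[str(ind_id)] = IndividualParams(
            beta=beta, gamma=vals["gamma"], theta=vals["theta"], sigma1_sq=vals["sigma1_sq"]
        )
    treatment: dict[str, TreatmentParams] = {}
    for group, grp in df[df["level"] == "treatment"].groupby("group"):
        vals = dict(zip(grp["parameter"], grp["value"]))
        mu_beta = np.array(
            [vals[f"mu_beta_{i}"] for i in range(sum(k.startswith("mu_beta_") for k in vals))]
        )
        k = len(mu_beta)
        Sigma = np.empty((k, k))
        for a in range(k):
            for b in range(a, k):
                Sigma[a, b] = Sigma[b, a] = vals[f"Sigma_beta_{a}_{b}"]
        treatment[str(group)] = TreatmentParams(
            mu_beta=mu_beta,
            Sigma_beta=Sigma,
            mu_logit_gamma=vals["mu_logit_gamma"],
            var_logit_gamma=vals["var_logit_gamma"],
            mu_theta=vals["mu_theta"],
            var_theta=vals["var_theta"],
            mu_log_sigma1=vals["mu_log_sigma1"],
            var_log_sigma1=vals["var_log_sigma1"],
        )
    return individual, treatment


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Iteration defaults mirror the full-scale analysis: 100,000 first-stage
    iterations per individual, 50,000 second-stage iterations with the
    first 10% discarded as burn-in, and 1,000 Monte Carlo draws per
    iteration for back-transformed group means.
    """

    output_dir: str = "movemix_run"
    trajectories: str = "trajectories.csv"
    raster: str = "landscape.asc"
    master_seed: int = 0
    stage1_iters: int = 100_000
    stage2_iters: int = 50_000
    burn_in_frac: float = 0.1
    stage1_burn_in_frac: float = 0.0
    n_mc: int = 1000
    ci_level: float = 0.95
    beta_cov_model: str = "wishart"
    # synthetic-study knobs (used by the simulate command)
    n_individuals: int = 28
    length_min: int = 5
    length_max: int = 77
    raster_cols: int = 200
    raster_rows: int = 200
    raster_cell_size: float = 10.0
    hyperprior_overrides: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
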