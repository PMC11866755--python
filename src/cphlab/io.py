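"""File formats and run configuration.

Lambda trajectories use a columnar xvg-style text dialect: ``#`` lines are
free comments, ``#%json`` lines carry a JSON metadata block (pH, seeds, bias
parameters, site registry), ``@`` lines hold column legends, and data rows
are ``time  lambda...  censor`` with one lambda column per coordinate in
site-major order (lambda_p then lambda_t) and a final integer censor flag.
Round trips are lossless, including censor flags and metadata.

Run configuration is an mdp-like ``key = value`` text format whose keys are
named descriptively (an alias map hook allows engine-compatible spellings).
Unknown keys are rejected with a suggestion; defaults are the engine's
standard values.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field

import numpy as np

from .dbo import DBOConfig
from .dynamics import IntegratorConfig, LambdaTrajectory
from .scenarios import ScenarioSpec

__all__ = [
    "write_lambda_file",
    "read_lambda_file",
    "write_conf_matrix",
    "read_conf_matrix",
    "RunConfig",
    "parse_config",
    "read_config",
    "defaults_table",
    "KNOWN_KEYS",
]


# ---------------------------------------------------------------------------
# Lambda trajectory files


def write_lambda_file(path, traj: LambdaTrajectory) -> None:
    meta = dict(traj.metadata)
    meta["coord_ids"] = list(traj.coord_ids)
    with open(path, "w") as fh:
        fh.write("# constant-pH lambda trajectory\n")
        fh.write("#%json " + json.dumps(meta, default=_jsonable) + "\n")
        fh.write('@    title "lambda dynamics"\n')
        fh.write('@    xaxis  label "Time (ps)"\n')
        for k, cid in enumerate(traj.coord_ids):
            fh.write(f'@ s{k} legend "{cid}"\n')
        for i in range(traj.n_frames):
            vals = " ".join(f"{v:.6f}" for v in traj.lam[i])
            fh.write(f"{traj.times[i]:.4f} {vals} {int(traj.censored[i])}\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_lambda_file(path) -> LambdaTrajectory:
    """Parse a lambda trajectory file; lossless inverse of the writer.

    Distinct diagnostics for malformed headers, ragged rows (with line
    number) and non-monotone times.  Files with only ``@`` legends parse
    with empty metadata defaults.
    """
    meta: dict = {}
    legends: list[str] = []
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#%json"):
                try:
                    meta.update(json.loads(line[len("#%json"):].strip()))
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed JSON metadata header: {exc}"
                    ) from exc
                continue
            if line.startswith("#"):
                continue
            if line.startswith("@"):
                if "legend" in line:
                    try:
                        legends.append(line.split('"')[1])
                    except IndexError:
                        raise ValueError(
                            f"{path}:{lineno}: malformed legend line") from None
                continue
            parts = line.split()
            if ncol is None:
                ncol = len(parts)
                if ncol < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected at least 3 columns "
                        "(time, lambda..., censor)")
            elif len(parts) != ncol:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} columns, "
                    f"expected {ncol})")
            try:
                rows.append([float(v) for v in parts])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric data") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.array(rows)
    coord_ids = meta.pop("coord_ids", None) or legends or [
        f"coord{i}" for i in range(data.shape[1] - 2)]
    if len(coord_ids) != data.shape[1] - 2:
        raise ValueError(
            f"{path}: {len(coord_ids)} declared coordinates but "
            f"{data.shape[1] - 2} lambda columns")
    times = data[:, 0]
    if np.any(np.diff(times) <= 0):
        k = int(np.argmax(np.diff(times) <= 0))
        raise ValueError(f"{path}: time not strictly increasing at frame {k + 1}")
    return LambdaTrajectory(times=times, lam=data[:, 1:-1],
                            coord_ids=list(coord_ids),
                            censored=data[:, -1].astype(bool), metadata=meta)


def write_conf_matrix(path, traj: LambdaTrajectory) -> None:
    """Per-frame conformational coordinate matrix as plain TSV."""
    with open(path, "w") as fh:
        fh.write("time\t" + "\t".join(traj.conf_ids) + "\n")
        for i in range(traj.n_frames):
            vals = "\t".join(f"{v:.6f}" for v in traj.conf[i])
            fh.write(f"{traj.times[i]:.4f}\t{vals}\n")


def read_conf_matrix(path):
    """Returns (times, matrix, coord names)."""
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1:], header[1:]


# ---------------------------------------------------------------------------
# Run configuration

#: key -> (type, default, description).  Defaults are the standard engine
#: values; booleans are written yes/no.
KNOWN_KEYS: dict = {
    "lambda-dynamics": (bool, True, "enable lambda dynamics"),
    "simulation-ph": (float, 7.0, "simulation pH (single-run commands)"),
    "lambda-mass": (float, 60.0, "lambda particle mass (u)"),
    "lambda-dt": (float, 0.002, "lambda integration step (ps)"),
    "lambda-save-interval": (float, 0.5, "protonation state save interval (ps)"),
    "lambda-thermostat-tau": (float, 1.0, "CSVR thermostat coupling time (ps)"),
    "lambda-thermostat-temperature": (float, 300.0, "lambda thermostat temperature (K)"),
    "lambda-equilibration-time": (float, 50.0, "low-barrier equilibration run (ps)"),
    "double-well-barrier": (float, 6.0, "starting central barrier (kJ/mol)"),
    "dbo-adjust-wells": (bool, False, "enable dynamic well-position optimization"),
    "dbo-adjust-barrier": (bool, False, "enable dynamic barrier optimization"),
    "dbo-well-block": (float, 40.0, "well statistics block (ps)"),
    "dbo-occupancy-threshold": (float, 0.70, "well occupancy gate (fraction)"),
    "dbo-mean-tolerance": (float, 0.03, "well mean-lambda tolerance"),
    "dbo-shift-gain": (float, 0.5, "well shift gain"),
    "dbo-max-shift": (float, 0.08, "maximum cumulative well shift"),
    "dbo-barrier-block": (float, 1000.0, "barrier statistics block (ps)"),
    "dbo-barrier-increment": (float, 1.0, "barrier adjustment increment (kJ/mol)"),
    "dbo-barrier-min": (float, 1.0, "barrier lower clamp (kJ/mol)"),
    "dbo-barrier-max": (float, 20.0, "barrier upper clamp (kJ/mol)"),
    "dbo-target-fraction": (float, 0.25, "target in-transition frame fraction"),
    "dbo-fraction-tolerance": (float, 0.05, "in-transition fraction tolerance"),
    "dbo-censor-duration": (float, 10.0, "censoring window after adjustments (ps)"),
    "buffer-charge-deprot": (float, -0.834, "buffer oxygen charge, deprotonated (e)"),
    "buffer-charge-prot": (float, 0.166, "buffer oxygen charge, protonated (e)"),
    "scenario": (str, "single", "scenario tag (single | tautomer | coupled_pair"
                 " | conformation_coupled | spread_replica)"),
    "reference-pka": (float, 4.40, "reference pKa of the (first) site"),
    "micro-pka-delta": (float, 6.53, "microscopic delta-tautomer reference pKa"),
    "micro-pka-epsilon": (float, 6.92, "microscopic epsilon-tautomer reference pKa"),
    "second-site-pka": (float, 4.0, "reference pKa of the second site"),
    "coupling-w": (float, 0.0, "bilinear site-site coupling (kJ/mol)"),
    "conf-delta-pka": (float, 2.0, "pKa shift between conformational basins"),
    "conf-barrier": (float, 6.0, "conformational double-well barrier (kJ/mol)"),
    "conf-diffusion": (float, 0.05, "conformational diffusion coefficient (1/ps)"),
    "n-replicas": (int, 10, "replicas per pH point"),
    "replica-duration": (float, 2000.0, "sampling time per replica (ps)"),
    "ph-grid-step": (float, 0.5, "titration pH grid step"),
    "ph-grid-margin": (float, 1.0, "pH grid margin beyond extreme pKa values"),
    "seed": (int, 0, "global random seed"),
    "bootstrap-samples": (int, 5000, "bootstrap resamples for confidence intervals"),
}

#: hook for engine-compatible key spellings
KEY_ALIASES: dict = {}


@dataclass
class RunConfig:
    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        if key not in KNOWN_KEYS:
            raise KeyError(key)
        return self.values.get(key, KNOWN_KEYS[key][1])

    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(
            tag=self["scenario"], pka=self["reference-pka"],
            pka_micro_delta=self["micro-pka-delta"],
            pka_micro_epsilon=self["micro-pka-epsilon"],
            pka_second=self["second-site-pka"], coupling_w=self["coupling-w"],
            delta_pka=self["conf-delta-pka"], conf_barrier=self["conf-barrier"],
            conf_diffusion=self["conf-diffusion"],
            n_replicas=self["n-replicas"], duration=self["replica-duration"],
            ph_step=self["ph-grid-step"], ph_margin=self["ph-grid-margin"],
            seed=self["seed"])

    def integrator_config(self) -> IntegratorConfig:
        return IntegratorConfig(
            dt=self["lambda-dt"], save_interval=self["lambda-save-interval"],
            thermostat_tau=self["lambda-thermostat-tau"],
            thermostat_temperature=self["lambda-thermostat-temperature"],
            seed=self["seed"], equilibration=self["lambda-equilibration-time"])

    def dbo_config(self):
        if not (self["dbo-adjust-wells"] or self["dbo-adjust-barrier"]):
            return None
        return DBOConfig(
            well_block=self["dbo-well-block"],
            occupancy_threshold=self["dbo-occupancy-threshold"],
            mean_tolerance=self["dbo-mean-tolerance"],
            shift_gain=self["dbo-shift-gain"], max_shift=self["dbo-max-shift"],
            barrier_block=self["dbo-barrier-block"],
            increment=self["dbo-barrier-increment"],
            barrier_min=self["dbo-barrier-min"],
            barrier_max=self["dbo-barrier-max"],
            target_fraction=self["dbo-target-fraction"],
            fraction_tolerance=self["dbo-fraction-tolerance"],
            censor_duration=self["dbo-censor-duration"],
            start_barrier=self["double-well-barrier"],
            adjust_wells=self["dbo-adjust-wells"],
            adjust_barrier=self["dbo-adjust-barrier"])


def _coerce(key: str, raw: str):
    typ = KNOWN_KEYS[key][0]
    if typ is bool:
        low = raw.strip().lower()
        if low in ("yes", "true", "on", "1"):
            return True
        if low in ("no", "false", "off", "0"):
            return False
        raise ValueError(f"key {key!r}: expected yes/no, got {raw!r}")
    return typ(raw)


def parse_config(text: str) -> RunConfig:
    """Parse mdp-like ``key = value`` text; unknown keys are rejected."""
    values: dict = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split(";")[0].split("#")[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, raw = (p.strip() for p in line.split("=", 1))
        key = KEY_ALIASES.get(key, key)
        if key not in KNOWN_KEYS:
            hint = difflib.get_close_matches(key, KNOWN_KEYS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValueError(f"line {lineno}: unknown key {key!r}{suggestion}")
        values[key] = _coerce(key, raw)
    return RunConfig(values=values)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(fh.read())


def defaults_table() -> str:
    """Markdown table of every configuration key and its default value."""
    lines = ["| key | default | description |", "| --- | --- | --- |"]
    for key, (typ, default, desc) in KNOWN_KEYS.items():
        if typ is bool:
            shown = "yes" if default else "no"
        else:
            shown = repr(default) if typ is str else f"{default:g}" \
                if typ is float else str(default)
        lines.append(f"| `{key}` | {shown} | {desc} |")
    return "\n".join(lines) + "\n"
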