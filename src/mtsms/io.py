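"""HDF5 container I/O: raw k-space + truth sidecar, bins, subspaces, factors.

Layout: /kspace/{imaging,training}, /coils, /truth, /schedule (attrs; the
deterministic timetable is rebuilt on read), /bins, /subspaces, /factors.
Datasets are written with ``track_times=False`` so identical runs produce
bit-identical files.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .gating import BinAssignment
from .lrt import Phi
from .phantom import PhantomConfig, RawData
from .sequence import RelaxSubspaces, SequenceConfig, TissueParams, build_schedule

__all__ = ["save_raw", "load_raw", "save_bins", "load_bins",
           "save_subspaces", "load_subspaces", "save_factors", "load_factors"]


def _w(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def _phantom_cfg_json(cfg: PhantomConfig) -> str:
    d = dataclasses.asdict(cfg)
    d["tissues"] = {k: dataclasses.asdict(v) for k, v in cfg.tissues.items()}
    return json.dumps(d)


def _phantom_cfg_from_json(s: str) -> PhantomConfig:
    d = json.loads(s)
    d["tissues"] = {k: TissueParams(**v) for k, v in d["tissues"].items()}
    for key in ("slices", "flip_deg", "b1_range", "heart_center_mm",
                "outer_radius_mm", "wall_mm", "body_semiaxes_mm", "liver_x_mm"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return PhantomConfig(**d)


def save_raw(path: str, raw: RawData, mode: str = "w") -> None:
    with h5py.File(path, mode) as fh:
        ks = fh.create_group("kspace")
        _w(ks, "imaging", raw.imaging)
        _w(ks, "training", raw.training)
        _w(ks, "imaging_lines", raw.imaging_lines)
        _w(ks, "training_lines", raw.training_lines)
        _w(fh, "coils", raw.coils)
        fh.attrs["grid_n"] = raw.grid_n
        fh.attrs["oversample"] = raw.oversample
        fh.attrs["noise_sigma"] = raw.noise_sigma
        fh.attrs["seed"] = raw.seed

        sg = fh.create_group("schedule")
        scfg = raw.schedule.config
        for f in dataclasses.fields(scfg):
            v = getattr(scfg, f.name)
            sg.attrs[f.name] = v if not isinstance(v, tuple) else list(v)

        tg = fh.create_group("truth")
        for key in ("card_phase", "resp_phase", "resp_dy_mm", "resp_amp_scale",
                    "b1_maps", "support"):
            if key in raw.truth:
                _w(tg, key, np.asarray(raw.truth[key]))
        if "phantom_config" in raw.truth:
            tg.attrs["phantom_config"] = _phantom_cfg_json(raw.truth["phantom_config"])
        if "reference_params" in raw.truth:
            rg = tg.create_group("reference_params")
            for s, params in enumerate(raw.truth["reference_params"]):
                g = rg.create_group(f"slice{s}")
                for k, v in params.items():
                    _w(g, k, np.asarray(v))


def load_raw(path: str) -> RawData:
    with h5py.File(path, "r") as fh:
        sa = dict(fh["schedule"].attrs)
        scfg = SequenceConfig(
            tr_ms=float(sa["tr_ms"]), te_ms=float(sa["te_ms"]),
            flip_deg=tuple(sa["flip_deg"]), prep_ms=tuple(sa["prep_ms"]),
            recovery_ms=float(sa["recovery_ms"]), n_periods=int(sa["n_periods"]),
            train_first=bool(sa["train_first"]),
            golden_counter_all_lines=bool(sa.get("golden_counter_all_lines", False)),
        )
        schedule = build_schedule(scfg)
        truth = {}
        tg = fh["truth"]
        for key in tg:
            if key == "reference_params":
                truth[key] = [
                    {k: tg[key][sl][k][()] for k in tg[key][sl]}
                    for sl in sorted(tg[key])
                ]
            else:
                truth[key] = tg[key][()]
        if "support" in truth:
            truth["support"] = truth["support"].astype(bool)
        if "phantom_config" in tg.attrs:
            truth["phantom_config"] = _phantom_cfg_from_json(tg.attrs["phantom_config"])
        return RawData(
            imaging=fh["kspace/imaging"][()],
            training=fh["kspace/training"][()],
            imaging_lines=fh["kspace/imaging_lines"][()],
            training_lines=fh["kspace/training_lines"][()],
            coils=fh["coils"][()],
            schedule=schedule,
            grid_n=int(fh.attrs["grid_n"]),
            oversample=int(fh.attrs["oversample"]),
            noise_sigma=float(fh.attrs["noise_sigma"]),
            seed=int(fh.attrs["seed"]),
            truth=truth,
        )


def save_bins(path: str, bins: BinAssignment) -> None:
    with h5py.File(path, "a") as fh:
        if "bins" in fh:
            del fh["bins"]
        g = fh.create_group("bins")
        _w(g, "cardiac_bin", bins.cardiac_bin)
        _w(g, "resp_bin", bins.resp_bin)
        _w(g, "time_ms", bins.time_ms)
        _w(g, "resp_trace", bins.resp_trace)
        _w(g, "cardiac_phase", bins.cardiac_phase)
        g.attrs["n_card"] = bins.n_card
        g.attrs["n_resp"] = bins.n_resp
        g.attrs["end_expiration_bin"] = bins.end_expiration_bin


def load_bins(path: str) -> BinAssignment:
    with h5py.File(path, "r") as fh:
        g = fh["bins"]
        return BinAssignment(
            cardiac_bin=g["cardiac_bin"][()], resp_bin=g["resp_bin"][()],
            n_card=int(g.attrs["n_card"]), n_resp=int(g.attrs["n_resp"]),
            time_ms=g["time_ms"][()], resp_trace=g["resp_trace"][()],
            cardiac_phase=g["cardiac_phase"][()],
            end_expiration_bin=int(g.attrs["end_expiration_bin"]),
        )


def save_dictionary(path: str, dictionary) -> None:
    """Persist the dictionary's defining grids (atoms rebuild deterministically)."""
    with h5py.File(path, "a") as fh:
        if "dictionary" in fh:
            del fh["dictionary"]
        g = fh.create_group("dictionary")
        for name in ("t1_grid", "t2_grid", "b1_grid", "eff_grid", "n_grid", "n_full"):
            arr = getattr(dictionary, name)
            if arr is not None:
                _w(g, name, np.asarray(arr))
        g.attrs["tr_ms"] = dictionary.tr_ms


def load_dictionary(path: str):
    """Rebuild the dictionary from the stored grids and the schedule group."""
    from .sequence import build_dictionary

    with h5py.File(path, "r") as fh:
        g = fh["dictionary"]
        grids = tuple(g[name][()] for name in ("t1_grid", "t2_grid", "b1_grid",
                                               "eff_grid"))
        n_grid = g["n_grid"][()]
    schedule = load_raw(path).schedule
    train_n = np.unique(schedule.n_index[schedule.is_training])
    if n_grid.size > 1:
        pos = np.searchsorted(train_n, n_grid)
        decim = max(int(pos[1] - pos[0]), 1)
    else:
        decim = train_n.size
    return build_dictionary(schedule, grids, n_decim=decim)


def save_subspaces(path: str, sub: RelaxSubspaces) -> None:
    with h5py.File(path, "a") as fh:
        if "subspaces" in fh:
            del fh["subspaces"]
        g = fh.create_group("subspaces")
        for name in ("u_t1", "u_ta", "n_grid", "sv_t1", "sv_ta"):
            _w(g, name, getattr(sub, name))
        if sub.eval_table is not None:
            _w(g, "eval_table", sub.eval_table)
            _w(g, "eval_grid", sub.eval_grid)
        g.attrs["recon_error"] = sub.recon_error


def load_subspaces(path: str) -> RelaxSubspaces:
    with h5py.File(path, "r") as fh:
        g = fh["subspaces"]
        return RelaxSubspaces(
            u_t1=g["u_t1"][()], u_ta=g["u_ta"][()], n_grid=g["n_grid"][()],
            sv_t1=g["sv_t1"][()], sv_ta=g["sv_ta"][()],
            recon_error=float(g.attrs["recon_error"]),
            eval_table=g["eval_table"][()] if "eval_table" in g else None,
            eval_grid=g["eval_grid"][()] if "eval_grid" in g else None,
        )


def save_factors(path: str, phi: Phi, u_x: np.ndarray | None = None,
                 support: np.ndarray | None = None, trace=None) -> None:
    with h5py.File(path, "a") as fh:
        if "factors" in fh:
            del fh["factors"]
        g = fh.create_group("factors")
        _w(g, "core", phi.core)
        _w(g, "u_c", phi.u_c)
        _w(g, "u_r", phi.u_r)
        if u_x is not None:
            _w(g, "u_x", u_x)
        if support is not None:
            _w(g, "support", support)
        if trace is not None:
            _w(g, "objective_trace", np.asarray(
                [t["objective"] if isinstance(t, dict) else t for t in trace]))


def load_factors(path: str):
    """Returns (phi, u_x, support); the subspaces group must be present too."""
    sub = load_subspaces(path)
    with h5py.File(path, "r") as fh:
        g = fh["factors"]
        phi = Phi(core=g["core"][()], subspaces=sub, u_c=g["u_c"][()],
                  u_r=g["u_r"][()], n_grid=sub.n_grid)
        u_x = g["u_x"][()] if "u_x" in g else None
        support = g["support"][()].astype(bool) if "support" in g else None
    return phi, u_x, support
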