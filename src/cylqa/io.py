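"""Dataset containers, DICOM RT-DOSE reading, run configuration and pipeline.

Datasets round-trip through either an HDF5 container or a flat directory of
delimited-text matrices; both are bit-exact for float64.  The RT-DOSE reader
is a deliberately small parser for explicit-VR little-endian files carrying
the handful of attributes a dose grid needs (no general DICOM support is
installed in the runtime environment).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import struct
import time
from typing import Sequence

import h5py
import numpy as np
import yaml

from . import evaluate as ev
from . import model as mdl
from .dataset import augment, make_split, normalize_pair
from .gamma import CLINICAL_CRITERIA, GammaCriteria
from .simulate import (DetectorGeometry, DetectorMap, ErrorClass, ErrorSpec,
                       PlanSample, SimConfig, Technique, generate_dataset)

log = logging.getLogger("cylqa")

__all__ = [
    "save_dataset_hdf5", "load_dataset_hdf5",
    "save_dataset_text", "load_dataset_text",
    "save_map_text", "load_map_text",
    "read_rtdose", "RunConfig", "run_pipeline",
]

_TEXT_FMT = "%.17e"  # round-trips float64 exactly


def _sample_error(cls: int, magnitude: float, sign: int) -> ErrorSpec:
    if cls == int(ErrorClass.NORMAL):
        return ErrorSpec.normal()
    return ErrorSpec(ErrorClass(cls), magnitude, sign)


def save_dataset_hdf5(samples: Sequence[PlanSample],
                      path: str | pathlib.Path) -> None:
    geom = samples[0].calculated.geometry
    with h5py.File(path, "w") as f:
        f.attrs["n_axial"] = geom.n_axial
        f.attrs["n_circ"] = geom.n_circ
        f.attrs["radius"] = geom.radius
        f.attrs["axial_pitch"] = geom.axial_pitch
        f.create_dataset("calculated",
                         data=np.stack([s.calculated.values for s in samples]))
        f.create_dataset("measured",
                         data=np.stack([s.measured.values for s in samples]))
        f.create_dataset("label", data=np.array(
            [int(s.label.error_class) for s in samples]))
        f.create_dataset("magnitude", data=np.array(
            [s.label.magnitude for s in samples]))
        f.create_dataset("sign", data=np.array([s.label.sign for s in samples]))
        f.create_dataset("technique", data=np.array(
            [s.technique.value for s in samples], dtype="S8"))
        f.create_dataset("plan_id", data=np.array(
            [s.plan_id for s in samples], dtype="S32"))


def load_dataset_hdf5(path: str | pathlib.Path) -> list[PlanSample]:
    with h5py.File(path, "r") as f:
        geom = DetectorGeometry(
            n_axial=int(f.attrs["n_axial"]), n_circ=int(f.attrs["n_circ"]),
            radius=float(f.attrs["radius"]),
            axial_pitch=float(f.attrs["axial_pitch"]))
        calc = f["calculated"][:]
        meas = f["measured"][:]
        labels = f["label"][:]
        mags = f["magnitude"][:]
        signs = f["sign"][:]
        techniques = [t.decode() for t in f["technique"][:]]
        plan_ids = [p.decode() for p in f["plan_id"][:]]
    return [
        PlanSample(
            calculated=DetectorMap(calc[i], geom),
            measured=DetectorMap(meas[i], geom),
            label=_sample_error(int(labels[i]), float(mags[i]), int(signs[i])),
            technique=Technique(techniques[i]), plan_id=plan_ids[i])
        for i in range(len(plan_ids))]


def save_map_text(dmap: DetectorMap, path: str | pathlib.Path) -> None:
    np.savetxt(path, dmap.values, fmt=_TEXT_FMT, delimiter="\t")


def load_map_text(path: str | pathlib.Path,
                  geometry: DetectorGeometry | None = None) -> DetectorMap:
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    if geometry is None:
        geometry = DetectorGeometry(n_axial=values.shape[0],
                                    n_circ=values.shape[1])
    return DetectorMap(values, geometry)


def save_dataset_text(samples: Sequence[PlanSample],
                      out_dir: str | pathlib.Path) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geom = samples[0].calculated.geometry
    manifest = {"geometry": dataclasses.asdict(geom), "samples": []}
    for s in samples:
        save_map_text(s.calculated, out / f"{s.plan_id}_calc.tsv")
        save_map_text(s.measured, out / f"{s.plan_id}_meas.tsv")
        manifest["samples"].append({
            "plan_id": s.plan_id, "label": int(s.label.error_class),
            "magnitude": s.label.magnitude, "sign": s.label.sign,
            "technique": s.technique.value})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset_text(in_dir: str | pathlib.Path) -> list[PlanSample]:
    src = pathlib.Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    geom = DetectorGeometry(**manifest["geometry"])
    out = []
    for rec in manifest["samples"]:
        pid = rec["plan_id"]
        out.append(PlanSample(
            calculated=load_map_text(src / f"{pid}_calc.tsv", geom),
            measured=load_map_text(src / f"{pid}_meas.tsv", geom),
            label=_sample_error(rec["label"], rec["magnitude"], rec["sign"]),
            technique=Technique(rec["technique"]), plan_id=pid))
    return out


# --------------------------------------------------------------------------
# DICOM RT-DOSE reading (explicit VR little endian)

_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}


def _parse_elements(buf: bytes) -> dict[tuple[int, int], tuple[bytes, bytes]]:
    elements: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    pos = 0
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4:pos + 6]
        if not (vr.isalpha() and vr.isupper()):
            raise ValueError(
                f"unsupported transfer syntax (implicit VR?) at tag "
                f"({group:04x},{elem:04x})")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            pos += 8
        if length == 0xFFFFFFFF:
            raise ValueError(
                f"undefined-length element ({group:04x},{elem:04x}) not supported")
        elements[(group, elem)] = (vr, buf[pos:pos + length])
        pos += length
    return elements


def read_rtdose(path: str | pathlib.Path
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a DICOM RT-DOSE file (explicit VR little endian).

    Returns ``(dose, spacing, origin)`` where ``dose`` is a float array of
    shape (frames, rows, columns) scaled by DoseGridScaling, ``spacing`` the
    (row, column) pixel spacing in mm and ``origin`` the ImagePositionPatient.
    """
    raw = pathlib.Path(path).read_bytes()
    if len(raw) < 132 or raw[128:132] != b"DICM":
        raise ValueError(f"{path}: not a DICOM file (missing DICM marker)")
    el = _parse_elements(raw[132:])

    def get(tag: tuple[int, int], name: str) -> tuple[bytes, bytes]:
        if tag not in el:
            raise ValueError(f"{path}: missing required attribute {name}")
        return el[tag]

    def text(v: bytes) -> str:
        return v.decode().strip(" \x00")

    modality = text(get((0x0008, 0x0060), "Modality")[1])
    if modality != "RTDOSE":
        raise ValueError(f"{path}: not an RT-DOSE object (Modality={modality!r})")
    rows = struct.unpack("<H", get((0x0028, 0x0010), "Rows")[1])[0]
    cols = struct.unpack("<H", get((0x0028, 0x0011), "Columns")[1])[0]
    frames = 1
    if (0x0028, 0x0008) in el:
        frames = int(text(el[(0x0028, 0x0008)][1]) or 1)
    bits = struct.unpack("<H", get((0x0028, 0x0100), "BitsAllocated")[1])[0]
    scaling = float(text(get((0x3004, 0x000E), "DoseGridScaling")[1]))
    spacing = np.array([float(v) for v in
                        text(get((0x0028, 0x0030), "PixelSpacing")[1]).split("\\")])
    origin = np.zeros(3)
    if (0x0020, 0x0032) in el:
        origin = np.array([float(v) for v in
                           text(el[(0x0020, 0x0032)][1]).split("\\")])
    pixel = get((0x7FE0, 0x0010), "PixelData")[1]
    dtype = {16: np.uint16, 32: np.uint32}.get(bits)
    if dtype is None:
        raise ValueError(f"{path}: unsupported BitsAllocated={bits}")
    grid = np.frombuffer(pixel, dtype=dtype, count=frames * rows * cols)
    dose = grid.reshape(frames, rows, cols).astype(float) * scaling
    return dose, spacing, origin


# --------------------------------------------------------------------------
# Run configuration and the end-to-end pipeline

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """One file that reproduces a whole experiment."""

    sim: SimConfig = SimConfig()
    train: mdl.TrainConfig = mdl.TrainConfig()
    criteria: tuple[GammaCriteria, ...] = CLINICAL_CRITERIA
    split_seed: int = 0
    augment_factor: int = 5
    augment_seed: int = 0
    gamma_search_step: float | None = None
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"].pop("geometry")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        sim = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.get("sim", {}).items()})
        train = mdl.TrainConfig(**d.get("train", {}))
        criteria = tuple(GammaCriteria(**c) for c in d["criteria"]) \
            if "criteria" in d else CLINICAL_CRITERIA
        return cls(sim=sim, train=train, criteria=criteria,
                   split_seed=d.get("split_seed", 0),
                   augment_factor=d.get("augment_factor", 5),
                   augment_seed=d.get("augment_seed", 0),
                   gamma_search_step=d.get("gamma_search_step"),
                   verbosity=d.get("verbosity", "INFO"))

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["criteria"] = [dataclasses.asdict(c) for c in self.criteria]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | pathlib.Path) -> dict:
    """simulate -> split -> augment -> 5-fold train -> predict -> gamma -> report.

    Writes every artifact under ``out_dir`` stamped with the config hash;
    reruns with the same config produce identical manifests.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    stamp = {"config_hash": config.config_hash}
    (out / "config.yaml").write_text(config.to_yaml())

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s ...", name)
        return time.perf_counter()

    try:
        t = stage("simulate")
        samples = generate_dataset(config.sim)
        save_dataset_hdf5(samples, out / "dataset.h5")
        log.info("stage simulate done in %.1fs (%d samples)",
                 time.perf_counter() - t, len(samples))

        t = stage("split")
        split = make_split(samples, seed=config.split_seed)
        (out / "split.json").write_text(json.dumps(
            {**split.to_dict(), **stamp}, indent=2))

        t = stage("augment")
        by_id = {s.plan_id: s for s in samples}
        train_instances = augment(
            [normalize_pair(by_id[pid]) for pid in split.train_ids],
            factor=config.augment_factor, seed=config.augment_seed)
        test_samples = [by_id[pid] for pid in split.test_ids]
        test_instances = [normalize_pair(s) for s in test_samples]

        t = stage("train")
        ensemble = mdl.crossval_train(train_instances, split, config.train)
        mdl.save_ensemble(ensemble, out / "model")
        log.info("stage train done in %.1fs (fold val acc %s)",
                 time.perf_counter() - t, ensemble.fold_val_accuracy)

        t = stage("predict")
        probs, labels = mdl.predict(ensemble, test_instances)
        (out / "predictions.json").write_text(json.dumps({
            **stamp,
            "plan_ids": list(split.test_ids),
            "probabilities": probs.tolist(),
            "labels": labels.tolist()}, indent=2))

        t = stage("evaluate")
        report = ev.build_report(probs, test_samples, config.criteria,
                                 search_step=config.gamma_search_step)
        (out / "report.json").write_text(json.dumps(
            {**stamp, **report.to_dict()}, indent=2))
        report.binary_table.to_csv(out / "binary_table.csv", index=False)
        log.info("stage evaluate done in %.1fs", time.perf_counter() - t)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage '{current['stage']}': {exc}") from exc
    return {"out_dir": str(out), **stamp,
            "test_accuracy": float(
                (labels == np.array([int(s.label.error_class)
                                     for s in test_samples])).mean())}
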