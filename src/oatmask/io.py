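"""HDF5 dataset containers and mask export.

One HDF5 file carries a full acquisition: /config (scan + detector +
code parameters, units mm/us/MHz), /code/bits (the generating twin-prime
sequence; W is regenerated on load, never stored), /sources, /Y and
/t_sampled, and optionally /volume and /maps after reconstruction.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .codes import (CodingMatrix, CyclicSCode, MaskLayout,
                    build_coding_matrix, fold_to_mask)
from .simulate import DetectorModel, MultiplexedData, PointSource, ScanConfig

__all__ = ["save_dataset", "load_dataset", "save_volume", "export_mask"]

_SCAN_FIELDS = ("pitch", "alpha", "beta", "d", "c", "fs", "n_t", "t0",
                "noise_sigma", "seed")
_DET_FIELDS = ("band_low", "band_high", "filter_order", "detector_diameter")


def save_dataset(path: str | Path, data: MultiplexedData, mask: MaskLayout,
                 det: DetectorModel, sources: list[PointSource] | None = None,
                 extra_config: dict | None = None) -> None:
    """Write a multiplexed acquisition to an HDF5 container."""
    with h5py.File(path, "w") as f:
        cfg = f.create_group("config")
        for k in _SCAN_FIELDS:
            cfg.attrs[k] = getattr(data.scan, k)
        for k in _DET_FIELDS:
            cfg.attrs[k] = getattr(det, k)
        cfg.attrs["units"] = "mm / us / MHz"
        if extra_config:
            cfg.attrs["extra"] = json.dumps(extra_config)
        code = f.create_group("code")
        code.create_dataset("bits", data=mask.code.bits)
        code.attrs["P"] = mask.code.P
        code.attrs["Q"] = mask.code.Q
        code.attrs["pitch"] = mask.pitch
        code.attrs["aperture_diameter"] = mask.aperture_diameter
        if sources:
            f.create_dataset(
                "sources",
                data=np.array([(*s.position, s.amplitude) for s in sources]))
        f.create_dataset("Y", data=data.Y)
        f.create_dataset("t_sampled", data=data.t_sampled)


def load_dataset(path: str | Path) -> tuple[MultiplexedData, MaskLayout,
                                            CodingMatrix, DetectorModel,
                                            list[PointSource]]:
    """Read an acquisition container; W is rebuilt from the stored code."""
    with h5py.File(path, "r") as f:
        if "Y" not in f or "config" not in f:
            raise ValueError(f"{path}: not an acquisition container "
                             "(missing /Y or /config)")
        cfg = f["config"].attrs
        scan = ScanConfig(**{k: (int(cfg[k]) if k in ("alpha", "beta", "n_t", "seed")
                                 else float(cfg[k])) for k in _SCAN_FIELDS})
        det = DetectorModel(band_low=float(cfg["band_low"]),
                            band_high=float(cfg["band_high"]),
                            filter_order=int(cfg["filter_order"]),
                            detector_diameter=float(cfg["detector_diameter"]))
        code = CyclicSCode(P=int(f["code"].attrs["P"]),
                           Q=int(f["code"].attrs["Q"]),
                           bits=f["code/bits"][...])
        mask = fold_to_mask(code, float(f["code"].attrs["pitch"]),
                            float(f["code"].attrs["aperture_diameter"]))
        sources = []
        if "sources" in f:
            sources = [PointSource(position=tuple(row[:3]), amplitude=row[3])
                       for row in f["sources"][...]]
        data = MultiplexedData(Y=f["Y"][...], t_sampled=f["t_sampled"][...],
                               offsets=scan.offsets, scan=scan)
    return data, mask, build_coding_matrix(code), det, sources


def save_volume(path: str | Path, vol, maps: dict[str, np.ndarray] | None = None) -> None:
    """Append a reconstruction (and optional MAPs) to a container."""
    with h5py.File(path, "a") as f:
        for key in ("volume", "maps"):
            if key in f:
                del f[key]
        g = f.create_group("volume")
        g.create_dataset("values", data=vol.values)
        g.attrs["voxel_size"] = vol.voxel_size
        g.attrs["origin"] = vol.origin
        if maps:
            m = f.create_group("maps")
            for name, img in maps.items():
                m.create_dataset(name, data=img)


def export_mask(mask: MaskLayout, basepath: str | Path) -> list[Path]:
    """Write the extended physical mask as CSV + PNG + JSON sidecar.

    PNG: white = aperture (open), black = blocked.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    np.savetxt(csv_path, mask.extended, fmt="%d", delimiter=",")
    png_path = base.with_suffix(".png")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.imsave(png_path, mask.extended, cmap="gray", vmin=0, vmax=1)
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps({
        "P": mask.P, "Q": mask.Q, "N": mask.code.N,
        "pitch_mm": mask.pitch,
        "aperture_diameter_mm": mask.aperture_diameter,
        "aperture_area_mm2": mask.aperture_area,
        "extended_shape": list(mask.extended.shape),
        "extended_sites": int(mask.extended.size),
        "open_fraction": float(mask.code.bits.mean()),
    }, indent=2))
    return [csv_path, png_path, json_path]
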