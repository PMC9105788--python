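"""Raw-data container: in-memory RadialStack and its HDF5 schema.

The native container is a plain HDF5 file::

    /data        complex (view, kz, readout, coil)
    /angles      float   (view,)           degrees
    /kz_order    int     (kz,)
    /k_radial    float   (readout,)        cycles/FOV
    /timestamps  float   (view*kz,)        ms
    attrs: n_views, nz, n_read, matrix, fov_xy, fov_z, tr, te, fa,
           segment_bounds, n_pre, n_ramp, provenance

An ISMRMRD-flavored layout (acquisition data + header attributes) can be
imported through :func:`read_ismrmrd_like`.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .trajectory import ProtocolParams, Trajectory

__all__ = ["RadialStack", "read_raw", "write_raw", "read_ismrmrd_like"]

_REQUIRED = ("data", "angles", "kz_order", "k_radial", "timestamps")
_PROTO_ATTRS = ("n_views", "nz", "n_read", "matrix", "fov_xy", "fov_z",
                "tr", "te", "fa", "n_pre", "n_ramp")


@dataclass
class RadialStack:
    """Multi-coil radial stack-of-stars k-space data with its trajectory
    and protocol; the pipeline's raw input."""

    data: np.ndarray          # complex (view, kz, readout, coil)
    traj: Trajectory
    protocol: ProtocolParams
    provenance: str = ""

    def __post_init__(self) -> None:
        nv, nz, nk, _ = self.data.shape
        if nv != self.protocol.n_views or nz != self.protocol.nz:
            raise ValueError("data dimensions inconsistent with protocol")
        if self.traj.angles.size != nv or self.traj.k_radial.size != nk:
            raise ValueError("trajectory inconsistent with data dimensions")

    @property
    def n_coils(self) -> int:
        return self.data.shape[-1]

    def view_slice(self, views) -> np.ndarray:
        return self.data[np.asarray(views)]


def write_raw(path, stack: RadialStack) -> None:
    """Write the stack losslessly to the native HDF5 schema."""
    p, t = stack.protocol, stack.traj
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=stack.data)
        f.create_dataset("angles", data=t.angles)
        f.create_dataset("kz_order", data=t.kz_order)
        f.create_dataset("k_radial", data=t.k_radial)
        f.create_dataset("timestamps", data=t.timestamps)
        for name in _PROTO_ATTRS:
            f.attrs[name] = getattr(p, name)
        f.attrs["segment_bounds"] = np.asarray(p.segment_bounds, dtype=np.int64)
        f.attrs["provenance"] = stack.provenance


def read_raw(path) -> RadialStack:
    """Read a native container; missing datasets raise a schema error
    naming the dataset."""
    with h5py.File(path, "r") as f:
        for name in _REQUIRED:
            if name not in f:
                raise KeyError(f"raw container missing required dataset '{name}'")
        kwargs = {name: f.attrs[name] for name in _PROTO_ATTRS}
        for name in ("n_views", "nz", "n_read", "matrix", "n_pre", "n_ramp"):
            kwargs[name] = int(kwargs[name])
        proto = ProtocolParams(
            segment_bounds=tuple(int(b) for b in f.attrs["segment_bounds"]),
            **kwargs)
        traj = Trajectory(angles=f["angles"][:], kz_order=f["kz_order"][:],
                          k_radial=f["k_radial"][:],
                          timestamps=f["timestamps"][:])
        return RadialStack(data=f["data"][:], traj=traj, protocol=proto,
                           provenance=str(f.attrs.get("provenance", "")))


def read_ismrmrd_like(path) -> RadialStack:
    """Import an ISMRMRD-flavored HDF5 layout.

    Expects ``/dataset/data`` shaped (view, kz, readout, coil) with a
    ``/dataset`` attribute group carrying the minimal acquisition header:
    trajectory angles/k_radial and the sequence attributes named as in the
    native schema (matrix, fov, TR/TE/FA, segment bounds).  Headers are
    mapped onto :class:`ProtocolParams`; missing timing is synthesized
    from TR.
    """
    with h5py.File(path, "r") as f:
        if "dataset" not in f or "data" not in f["dataset"]:
            raise KeyError("ISMRMRD-like container missing '/dataset/data'")
        g = f["dataset"]
        data = g["data"][:]
        nv, nz, nk, _ = data.shape
        attrs = dict(g.attrs)
        proto = ProtocolParams(
            n_views=nv, nz=nz, n_read=nk,
            matrix=int(attrs["matrix"]),
            fov_xy=float(attrs["fov_xy"]), fov_z=float(attrs["fov_z"]),
            tr=float(attrs["tr"]), te=float(attrs["te"]),
            fa=float(attrs["fa"]),
            segment_bounds=tuple(int(b) for b in
                                 attrs.get("segment_bounds", ())),
        )
        angles = (g["angles"][:] if "angles" in g
                  else np.mod(np.arange(nv) * float(attrs["angle_increment"]),
                              360.0))
        k_radial = (g["k_radial"][:] if "k_radial" in g
                    else np.linspace(0, proto.matrix / 2, nk))
        ts = (g["timestamps"][:] if "timestamps" in g
              else np.arange(nv * nz, dtype=float) * proto.tr)
        traj = Trajectory(angles=angles, kz_order=np.arange(nz),
                          k_radial=k_radial, timestamps=ts)
        return RadialStack(data=data, traj=traj, protocol=proto,
                           provenance=str(attrs.get("provenance", "ismrmrd")))
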