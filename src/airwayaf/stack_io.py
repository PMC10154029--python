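"""Reading, validating and writing multichannel 3D autofluorescence stacks.

The in-memory container is :class:`MultiChannelStack`: three mandatory
channels (NAD(P)H, FAD, SHG) plus arbitrary named extras (e.g. ``fitc``,
``membrane``), all stored as ``(z, y, x)`` float arrays with an explicit
voxel geometry.  On-disk format is OME-TIFF (or plain multi-page TIFF),
written and parsed with :mod:`tifffile`.

Conventions
-----------
* 0-based voxel indices, arrays ordered ``(z, y, x)``.
* Canonical z orientation: the z index increases from tissue (basement
  membrane side) toward the lumen.  Loaders flip stacks declaring the
  opposite, so "apical" is always "larger z" downstream.
* Intensities are floats after load, regardless of on-disk bit depth;
  nothing is normalized at load time.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: canonical orientation flag: z index increases tissue -> lumen
TISSUE_TO_LUMEN = "tissue_to_lumen"
LUMEN_TO_TISSUE = "lumen_to_tissue"

#: fallback voxel size (dx, dy, dz) in micrometres when metadata is absent.
#: dz = 0.5 um axial step; the lateral pitch is an estimate for a 25x lens
#: at 2x zoom and a 1024x1024 scan, and should be overridden when known.
DEFAULT_VOXEL_SIZE = (0.25, 0.25, 0.5)

CORE_CHANNELS = ("nadph", "fad", "shg")


class StackIOError(ValueError):
    """Raised for malformed stacks, layouts or channel mappings."""


@dataclass
class MultiChannelStack:
    """Aligned 3D volumes for NAD(P)H, FAD and SHG plus named extras.

    Parameters
    ----------
    nadph, fad, shg
        ``(z, y, x)`` intensity volumes in detector units, non-negative.
    extra
        Optional named channels sharing the same shape (``fitc``,
        ``membrane``, ...).
    voxel_size
        ``(dx, dy, dz)`` in micrometres, all positive.
    z_orientation
        Either ``"tissue_to_lumen"`` (canonical) or ``"lumen_to_tissue"``.
    metadata
        Free-form acquisition notes, carried through I/O when possible.
    """

    nadph: np.ndarray
    fad: np.ndarray
    shg: np.ndarray
    extra: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    z_orientation: str = TISSUE_TO_LUMEN
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nadph = np.asarray(self.nadph, dtype=np.float64)
        self.fad = np.asarray(self.fad, dtype=np.float64)
        self.shg = np.asarray(self.shg, dtype=np.float64)
        self.extra = {k: np.asarray(v, dtype=np.float64) for k, v in self.extra.items()}
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        shape = self.nadph.shape
        if self.nadph.ndim != 3 or 0 in shape:
            raise StackIOError(f"unsupported layout: channel shape {shape}")
        for name, vol in self.channels().items():
            if vol.shape != shape:
                raise StackIOError(
                    f"geometry error: channel {name!r} shape {vol.shape} != {shape}"
                )
            if np.any(vol < 0):
                raise StackIOError(f"corrupt data: negative intensities in {name!r}")
        if len(set(self.channels())) != 3 + len(self.extra):
            raise StackIOError("channel names not unique")
        if any(v <= 0 for v in self.voxel_size):
            raise StackIOError(f"voxel dimensions must be positive: {self.voxel_size}")
        if self.z_orientation not in (TISSUE_TO_LUMEN, LUMEN_TO_TISSUE):
            raise StackIOError(f"unknown z orientation {self.z_orientation!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.nadph.shape

    def channels(self) -> dict[str, np.ndarray]:
        """All channels by name; core channels first, stable order."""
        out = {"nadph": self.nadph, "fad": self.fad, "shg": self.shg}
        out.update(self.extra)
        return out

    def total_autofluorescence(self) -> np.ndarray:
        """NAD(P)H + FAD, the combined metabolic autofluorescence."""
        return self.nadph + self.fad

    def to_canonical(self) -> "MultiChannelStack":
        """Return a copy flipped along z if declared lumen-to-tissue."""
        if self.z_orientation == TISSUE_TO_LUMEN:
            return self
        flipped = {k: v[::-1].copy() for k, v in self.channels().items()}
        return MultiChannelStack(
            nadph=flipped.pop("nadph"),
            fad=flipped.pop("fad"),
            shg=flipped.pop("shg"),
            extra=flipped,
            voxel_size=self.voxel_size,
            z_orientation=TISSUE_TO_LUMEN,
            metadata=dict(self.metadata),
        )

    def with_channels(self, **replacements: np.ndarray) -> "MultiChannelStack":
        """Copy of the stack with named channels replaced."""
        chans = {k: v.copy() for k, v in self.channels().items()}
        chans.update(replacements)
        return MultiChannelStack(
            nadph=chans.pop("nadph"),
            fad=chans.pop("fad"),
            shg=chans.pop("shg"),
            extra=chans,
            voxel_size=self.voxel_size,
            z_orientation=self.z_orientation,
            metadata=dict(self.metadata),
        )


@dataclass
class LabelVolume:
    """Per-cell 3D label mask: 0 = background, k > 0 = cell k."""

    labels: np.ndarray
    type_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise StackIOError("unsupported layout: label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise StackIOError("corrupt data: non-integer labels")
            self.labels = as_int
        if self.labels.min() < 0:
            raise StackIOError("corrupt data: negative labels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _axes_to_zcyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile series to (Z, C, Y, X), tolerating T/S singletons."""
    axes = axes.upper()
    # squeeze singleton axes we do not model (time, sample)
    for ax in ("T", "S", "Q", "I"):
        while ax in axes:
            idx = axes.index(ax)
            if data.shape[idx] != 1:
                if ax in ("Q", "I") and "Z" not in axes:
                    # generic/unknown axis standing in for Z
                    axes = axes[:idx] + "Z" + axes[idx + 1:]
                    break
                raise StackIOError(
                    f"unsupported layout: non-singleton axis {ax!r} in {axes!r}"
                )
            data = np.squeeze(data, axis=idx)
            axes = axes[:idx] + axes[idx + 1:]
    if sorted(axes) == ["X", "Y", "Z"]:
        data = np.moveaxis(data, [axes.index(a) for a in "ZYX"], [0, 1, 2])
        return data[:, None, :, :]
    if sorted(axes) == ["C", "X", "Y", "Z"]:
        return np.moveaxis(data, [axes.index(a) for a in "ZCYX"], [0, 1, 2, 3])
    raise StackIOError(f"unsupported layout: axes {axes!r}")


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    import re

    def grab(attr: str) -> float | None:
        m = re.search(rf'PhysicalSize{attr}="([0-9.eE+-]+)"', meta)
        return float(m.group(1)) if m else None

    dx, dy, dz = grab("X"), grab("Y"), grab("Z")
    if dx and dy and dz:
        return (dx, dy, dz)
    return None


def read_stack(
    path: str | Path,
    channel_map: dict[str, int],
    voxel_size: tuple[float, float, float] | None = None,
    z_orientation: str = TISSUE_TO_LUMEN,
) -> MultiChannelStack:
    """Read a TIFF/OME-TIFF volume into a validated :class:`MultiChannelStack`.

    Parameters
    ----------
    path
        TIFF or OME-TIFF whose axes resolve to (Z, C, Y, X) or a stated
        permutation; 3-axis files are treated as single-channel.
    channel_map
        Maps channel names to channel indices; must cover ``nadph``,
        ``fad`` and ``shg``.  Extra entries become named extra channels.
    voxel_size
        Caller-supplied ``(dx, dy, dz)`` in um, used when the file carries
        no geometry; file metadata wins when present.
    z_orientation
        Orientation the file was acquired in; the returned stack is always
        flipped to the canonical tissue-to-lumen convention.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        file_voxel = _voxel_size_from_ome(tif)

    zcyx = _axes_to_zcyx(np.asarray(data), axes)
    n_chan = zcyx.shape[1]
    missing = [k for k in CORE_CHANNELS if k not in channel_map]
    if missing:
        raise StackIOError(f"channel mapping error: missing {missing}")
    for name, idx in channel_map.items():
        if not 0 <= idx < n_chan:
            raise StackIOError(
                f"channel mapping error: {name!r} -> {idx} but file has {n_chan} channel(s)"
            )
    if np.any(zcyx < 0):
        raise StackIOError("corrupt data: negative intensities on disk")

    vols = {name: zcyx[:, idx].astype(np.float64) for name, idx in channel_map.items()}
    vs = file_voxel or voxel_size or DEFAULT_VOXEL_SIZE
    stack = MultiChannelStack(
        nadph=vols.pop("nadph"),
        fad=vols.pop("fad"),
        shg=vols.pop("shg"),
        extra=vols,
        voxel_size=vs,
        z_orientation=z_orientation,
        metadata={"source": str(path)},
    )
    return stack.to_canonical()


def write_stack(stack: MultiChannelStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF with channel names and voxel size recorded.

    ``read_stack(write_stack(s)) == s`` on channel data and voxel size.
    """
    path = Path(path)
    stack.validate()
    chans = stack.channels()
    data = np.stack(list(chans.values()), axis=1)  # (Z, C, Y, X)
    dx, dy, dz = stack.voxel_size
    tifffile.imwrite(
        path,
        data.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZCYX",
            "Channel": {"Name": list(chans)},
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def channel_names_in_file(path: str | Path) -> list[str]:
    """Channel names recorded in an OME-TIFF written by :func:`write_stack`."""
    import re

    with tifffile.TiffFile(path) as tif:
        meta = tif.ome_metadata or ""
    return re.findall(r'Channel[^>]*Name="([^"]+)"', meta)


def read_labels(path: str | Path, types_csv: str | Path | None = None) -> LabelVolume:
    """Read a 3D label TIFF, optionally with a label->cell_type CSV sidecar.

    The sidecar has columns ``label`` and ``cell_type``.
    """
    labels = tifffile.imread(path)
    type_of: dict[int, str] = {}
    if types_csv is not None:
        with open(types_csv, newline="") as fh:
            for row in csv.DictReader(fh):
                type_of[int(row["label"])] = row["cell_type"].strip()
    return LabelVolume(labels=np.asarray(labels), type_of=type_of)


def write_labels(vol: LabelVolume, path: str | Path, types_csv: str | Path | None = None) -> None:
    """Write a label volume as TIFF, optionally with its type-map sidecar."""
    tifffile.imwrite(path, vol.labels.astype(np.int32), photometric="minisblack")
    if types_csv is not None and vol.type_of:
        with open(types_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "cell_type"])
            for label in sorted(vol.type_of):
                writer.writerow([label, vol.type_of[label]])


def check_connected_labels(vol: LabelVolume) -> list[int]:
    """Return label ids that split into more than one connected component."""
    from scipy import ndimage

    bad = []
    for label in vol.ids():
        _, n = ndimage.label(vol.labels == label)
        if n > 1:
            bad.append(int(label))
    if bad:
        warnings.warn(f"labels with multiple connected components: {bad}")
    return bad
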