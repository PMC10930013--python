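"""Pseudo and real noise maps, and the patch training set built from them.

The denoising network is trained on *noise maps* rather than on CT images:

* the **real noise map** ``sigma_real = I_thin - I_3mm`` is the training
  label — the quantum-noise excess of the thin slice over its 3-mm
  partner, free of anatomy because both images share the same content;
* the **pseudo noise map** ``sigma_pseudo = I_thin - smooth(I_thin)`` is
  the network input, where the smoothed image is obtained by 2x2 block
  averaging (512 -> 256) followed by bicubic upsampling (256 -> 512).
  It approximates the high-frequency noise content of the thin slice and
  is computable without a paired scan, which is what makes the method
  applicable to patient images.

Maps are kept in float64.  Because CT pixels are float32, the difference
of two images is exact in float64, which makes the subtraction identity
``thin - sigma_real == thick`` hold at bit level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cacdn.phantoms import CTImage, GridSpec

PATCH_SIZE = 25
PATCH_STRIDE = 25


@dataclass
class NoiseMap:
    """Signed HU-valued noise map on the grid of its parent image."""

    values: np.ndarray          # float64, HU
    role: str                   # real | pseudo | predicted
    z: float                    # slice thickness of the parent thin image
    grid: GridSpec
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("real", "pseudo", "predicted"):
            raise ValueError(f"unknown noise-map role {self.role!r}")
        if self.role == "real" and self.z >= 3.0:
            raise ValueError("a real noise map requires a thin parent image")


@dataclass
class PatchSet:
    """Aligned input/label sub-image pairs with full origin bookkeeping."""

    inputs: np.ndarray          # (N, p, p)
    labels: np.ndarray          # (N, p, p)
    patch_size: int
    stride: int
    provenance: list[tuple[int, int, int]]  # (dataset, row, col)
    shuffle_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels must be aligned")
        if len(self.provenance) != len(self.inputs):
            raise ValueError("provenance must cover every patch")

    def __len__(self) -> int:
        return len(self.inputs)

    def concat(self, other: "PatchSet") -> "PatchSet":
        if (self.patch_size, self.stride) != (other.patch_size, other.stride):
            raise ValueError("patch geometry mismatch")
        return PatchSet(
            inputs=np.concatenate([self.inputs, other.inputs]),
            labels=np.concatenate([self.labels, other.labels]),
            patch_size=self.patch_size, stride=self.stride,
            provenance=self.provenance + other.provenance,
        )


def _require_same_grid(a_grid: GridSpec, b_grid: GridSpec) -> None:
    if a_grid != b_grid:
        raise ValueError("images are on different grids")


def real_noise_map(thick: CTImage, thin: CTImage) -> NoiseMap:
    """Label map: thin minus 3-mm image, so ``thin - map == thick``."""
    _require_same_grid(thick.grid, thin.grid)
    if thin.slice_thickness not in (0.5, 1.0, 1.5):
        raise ValueError("thin image must have z in {0.5, 1.0, 1.5} mm")
    if thick.slice_thickness != 3.0:
        raise ValueError("reference image must be the 3-mm reconstruction")
    values = thin.pixels.astype(np.float64) - thick.pixels.astype(np.float64)
    return NoiseMap(values=values, role="real", z=thin.slice_thickness,
                    grid=thin.grid,
                    provenance=f"real({thin.provenance})")


def block_downsample(image: np.ndarray) -> np.ndarray:
    """2x2 block mean, halving each dimension; preserves the global mean."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    if h % 2 or w % 2:
        raise ValueError("image dimensions must be even")
    return image.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def _keys_kernel(d: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel (a = -0.5)."""
    d = np.abs(d)
    out = np.zeros_like(d)
    m1 = d <= 1.0
    m2 = (d > 1.0) & (d < 2.0)
    out[m1] = (a + 2.0) * d[m1] ** 3 - (a + 3.0) * d[m1] ** 2 + 1.0
    out[m2] = a * d[m2] ** 3 - 5.0 * a * d[m2] ** 2 + 8.0 * a * d[m2] - 4.0 * a
    return out


def _upsample_matrix(n_in: int, factor: int = 2) -> np.ndarray:
    """Row-stochastic 1-D bicubic upsampling operator (half-pixel centres,
    edge-replicated borders)."""
    n_out = n_in * factor
    W = np.zeros((n_out, n_in))
    for i in range(n_out):
        x = (i + 0.5) / factor - 0.5  # source coordinate of output sample i
        m = int(np.floor(x))
        taps = np.arange(m - 1, m + 3)
        w = _keys_kernel(x - taps.astype(np.float64))
        taps = np.clip(taps, 0, n_in - 1)  # replicate edges
        for t, wt in zip(taps, w):
            W[i, t] += wt
    return W


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def bicubic_upsample(image: np.ndarray) -> np.ndarray:
    """2x bicubic upsampling (Keys a=-0.5, half-pixel-centre alignment).

    The output grid is aligned so that each 2x2 output block is centred on
    its source pixel — the inverse convention of ``block_downsample``.
    Constants and linear ramps are reproduced (up to rounding) away from
    the replicated border.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    for n in {h, w}:
        if n not in _UPSAMPLE_CACHE:
            _UPSAMPLE_CACHE[n] = _upsample_matrix(n)
    return _UPSAMPLE_CACHE[h] @ image @ _UPSAMPLE_CACHE[w].T


def smooth_image(image: np.ndarray) -> np.ndarray:
    """Low-frequency estimate: 2x2 block mean then bicubic upsample."""
    return bicubic_upsample(block_downsample(image))


def pseudo_noise_map(thin: CTImage) -> NoiseMap:
    """Input map: thin image minus its down/up-sampled smoothed self."""
    values = thin.pixels.astype(np.float64) - smooth_image(thin.pixels)
    return NoiseMap(values=values, role="pseudo", z=thin.slice_thickness,
                    grid=thin.grid,
                    provenance=f"pseudo({thin.provenance})")


def extract_patches(input_map: NoiseMap, label_map: NoiseMap,
                    patch: int = PATCH_SIZE, stride: int = PATCH_STRIDE,
                    dataset_index: int = 0) -> PatchSet:
    """Tile co-located input/label patches from a noise-map pair.

    Tiling starts at the image origin; any margin narrower than a patch on
    the right/bottom edge is discarded (a 512 grid with 25-px patches at
    stride 25 yields 20 x 20 = 400 patches and a 12-px margin).
    """
    _require_same_grid(input_map.grid, label_map.grid)
    h, w = input_map.values.shape
    if patch > min(h, w) or stride < 1:
        raise ValueError("invalid patch/stride for this grid")
    rows = range(0, h - patch + 1, stride)
    cols = range(0, w - patch + 1, stride)
    inputs, labels, prov = [], [], []
    for r in rows:
        for c in cols:
            inputs.append(input_map.values[r:r + patch, c:c + patch])
            labels.append(label_map.values[r:r + patch, c:c + patch])
            prov.append((dataset_index, r, c))
    return PatchSet(inputs=np.stack(inputs), labels=np.stack(labels),
                    patch_size=patch, stride=stride, provenance=prov)


def shuffle_patches(ps: PatchSet, seed: int) -> PatchSet:
    """Apply one seeded random permutation jointly to inputs, labels and
    provenance; the patch multiset is unchanged."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ps))
    return PatchSet(inputs=ps.inputs[perm], labels=ps.labels[perm],
                    patch_size=ps.patch_size, stride=ps.stride,
                    provenance=[ps.provenance[i] for i in perm],
                    shuffle_seed=seed)


def build_training_patches(pairs, patch: int = PATCH_SIZE,
                           stride: int = PATCH_STRIDE,
                           shuffle_seed: int | None = None) -> PatchSet:
    """Pseudo/real patch set over a list of simulated scan pairs."""
    ps: PatchSet | None = None
    for i, pair in enumerate(pairs):
        pmap = pseudo_noise_map(pair.thin)
        rmap = real_noise_map(pair.thick, pair.thin)
        one = extract_patches(pmap, rmap, patch, stride, dataset_index=i)
        ps = one if ps is None else ps.concat(one)
    if ps is None:
        raise ValueError("no scan pairs supplied")
    if shuffle_seed is not None:
        ps = shuffle_patches(ps, shuffle_seed)
    return ps
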