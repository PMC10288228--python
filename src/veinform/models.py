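"""Learned stages of the wing regeneration workflow.

Two models bridge the gap between a bare boundary outline and a full
reciprocal pair: an image-to-image *translator* that proposes the force
main-path raster for a boundary (with a deterministic geometric
fallback), and a vector *length regressor* mapping a dual edge's
endpoint coordinates and force magnitude ``(x1, y1, x2, y2, f)`` to the
length of the corresponding form edge.  The regressor follows
scikit-learn estimator conventions and composes with sklearn model
selection.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .errors import CodecError, TrainingError
from .reciprocal import ForceDiagram

#: rotation angles (degrees) used for training-set augmentation
AUGMENT_ANGLES = (-15, -10, -5, 0, 5, 10, 15)


@dataclass
class TrainConfig:
    """Hyperparameters shared by the learned stages."""

    seed: int = 0
    learning_rate: float = 1e-3
    hidden: tuple[int, ...] = (64, 64)
    epochs: int = 400
    batch_size: int = 32
    val_fraction: float = 0.2
    resolution: int = 32  # translator working resolution (<= 256)


# ---------------------------------------------------------------------------
# rotation augmentation


def _infer_background(img: np.ndarray) -> float:
    corners = [img[0, 0], img[0, -1], img[-1, 0], img[-1, -1]]
    return float(np.median([np.mean(c) for c in corners]))


def _rotate(img: np.ndarray, angle: float, background: float) -> np.ndarray:
    from scipy.ndimage import rotate as nd_rotate

    if angle == 0:
        return img.copy()
    out = nd_rotate(
        img.astype(float),
        angle,
        reshape=False,
        order=1,
        mode="constant",
        cval=background,
        axes=(1, 0),
    )
    if img.dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return out


def augment_rotations(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    angles: tuple[float, ...] = AUGMENT_ANGLES,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotate every (input, target) image pair by every angle.

    Both images of a pair are rotated by the same angle about the image
    center and padded with their background value, so labels stay
    consistent; the output has ``len(pairs) * len(angles)`` pairs.  If a
    rotation would clip non-background content, the canvas is padded
    first (with a warning).
    """
    out = []
    for src, dst in pairs:
        prepared = []
        for img in (src, dst):
            bg = _infer_background(img)
            content = (
                np.abs(img.astype(float) - bg).max(axis=-1)
                if img.ndim == 3
                else np.abs(img.astype(float) - bg)
            ) > 16
            pad = 0
            if content.any():
                ys, xs = np.nonzero(content)
                h, w = img.shape[:2]
                cy, cx = (h - 1) / 2, (w - 1) / 2
                r = float(np.hypot(ys - cy, xs - cx).max())
                room = min(cy, cx)
                if r > room - 1:
                    pad = int(np.ceil(r - room + 2))
                    warnings.warn(
                        f"rotation would clip content; padding canvas by {pad} px"
                    )
            if pad:
                widths = ((pad, pad), (pad, pad)) + (((0, 0),) if img.ndim == 3 else ())
                img = np.pad(img, widths, constant_values=img.dtype.type(bg))
            prepared.append((img, bg))
        for angle in angles:
            out.append(
                (
                    _rotate(prepared[0][0], angle, prepared[0][1]),
                    _rotate(prepared[1][0], angle, prepared[1][1]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# edge-length regressor


class LengthRegressor(BaseEstimator, RegressorMixin):
    """ANN mapping (x1, y1, x2, y2, f) to the form edge length.

    A small fully connected network on standardized features, trained
    with deterministic L-BFGS so a fixed ``random_state`` reproduces
    identical weights.  Inputs are the dual edge's endpoint coordinates
    normalized to the force diagram's bounding box and its force
    magnitude normalized by the maximum force; the target is the form
    edge length normalized by the form's bounding-box diagonal.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 64),
        activation: str = "tanh",
        max_iter: int = 4000,
        random_state: int = 0,
        alpha: float = 1e-4,
        tol: float = 1e-7,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.max_iter = max_iter
        self.random_state = random_state
        self.alpha = alpha
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 5:
            raise ValueError("X must be (n_samples, 5): x1, y1, x2, y2, f")
        self.scaler_ = StandardScaler().fit(X)
        self.net_ = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation=self.activation,
            solver="lbfgs",
            alpha=self.alpha,
            max_iter=self.max_iter,
            random_state=self.random_state,
            tol=self.tol,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.net_.fit(self.scaler_.transform(X), y)
        if not np.isfinite(self.net_.loss_):
            raise TrainingError(f"training diverged: loss {self.net_.loss_}")
        self.loss_ = float(self.net_.loss_)
        self.n_features_in_ = 5
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        return self.net_.predict(self.scaler_.transform(X))


@dataclass
class LengthModel:
    """A fitted regressor plus its provenance and normalization info."""

    regressor: LengthRegressor
    config: TrainConfig
    data_checksum: str
    train_loss: float
    val_r2: float
    history: dict = field(default_factory=dict)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def train_length_regressor(
    edge_features, config: TrainConfig | None = None
) -> LengthModel:
    """Fit the edge-length ANN on (x1, y1, x2, y2, f, target) records.

    Records are split into train/validation by the seeded RNG; the
    fitted model is returned with its validation R-squared and a data
    checksum for provenance.
    """
    config = config or TrainConfig()
    data = np.asarray(edge_features, dtype=float)
    if data.ndim != 2 or data.shape[1] != 6:
        raise TrainingError("edge features must be rows of (x1, y1, x2, y2, f, target)")
    if len(data) < 100:
        raise TrainingError(f"need >= 100 records, got {len(data)}")
    if not np.isfinite(data).all():
        raise TrainingError("non-finite values in the training data")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(data))
    n_val = max(1, int(round(config.val_fraction * len(data))))
    val, train = data[order[:n_val]], data[order[n_val:]]
    reg = LengthRegressor(
        hidden_layer_sizes=tuple(config.hidden),
        max_iter=config.epochs * 10,
        random_state=config.seed,
    )
    reg.fit(train[:, :5], train[:, 5])
    from sklearn.metrics import r2_score

    val_r2 = float(r2_score(val[:, 5], reg.predict(val[:, :5])))
    return LengthModel(
        regressor=reg,
        config=config,
        data_checksum=_checksum(data),
        train_loss=reg.loss_,
        val_r2=val_r2,
        history={"loss_curve": getattr(reg.net_, "loss_curve_", [])},
    )


def save_length_model(model: LengthModel, path) -> None:
    import joblib

    joblib.dump(model.regressor, path)
    with open(str(path) + ".json", "w") as fh:
        json.dump(
            {
                "config": asdict(model.config),
                "data_checksum": model.data_checksum,
                "train_loss": model.train_loss,
                "val_r2": model.val_r2,
            },
            fh,
            indent=1,
        )


def load_length_model(path) -> LengthModel:
    import joblib

    reg = joblib.load(path)
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    cfg = TrainConfig(**{**side["config"], "hidden": tuple(side["config"]["hidden"])})
    return LengthModel(
        regressor=reg,
        config=cfg,
        data_checksum=side["data_checksum"],
        train_loss=side["train_loss"],
        val_r2=side["val_r2"],
    )


def predict_lengths(
    model: LengthModel,
    force: ForceDiagram,
    form_scale: float,
    min_length_fraction: float = 1e-3,
) -> dict[int, float]:
    """Predict form edge lengths for every dual edge of a force diagram.

    Features are normalized exactly as in training; out-of-range inputs
    are clipped with a warning, and non-positive predictions floored at
    ``min_length_fraction * form_scale``.  Lengths come back in the
    units fixed by ``form_scale`` (the form's bounding-box diagonal).
    """
    pts = np.array([force.coords(v) for v in force.vertices])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    F = force.edge_lengths()
    f_max = max(F.values()) if F else 1.0
    rows, eids = [], []
    for de in force.edges:
        a = (force.coords(de.a) - lo) / span
        b = (force.coords(de.b) - lo) / span
        rows.append([a[0], a[1], b[0], b[1], F[de.form_edge_id] / f_max])
        eids.append(de.form_edge_id)
    X = np.asarray(rows, dtype=float)
    if (X[:, :4] < -1e-9).any() or (X[:, :4] > 1 + 1e-9).any():
        warnings.warn("coordinates outside [0, 1] after normalization; clipping")
        X[:, :4] = np.clip(X[:, :4], 0.0, 1.0)
    pred = model.regressor.predict(X) * form_scale
    floor = min_length_fraction * form_scale
    n_floored = int((pred <= 0).sum())
    if n_floored:
        warnings.warn(f"floored {n_floored} non-positive length predictions")
    return {eid: float(max(p, floor)) for eid, p in zip(eids, pred)}


# ---------------------------------------------------------------------------
# boundary -> main path translation


class MainPathTranslator(BaseEstimator):
    """Reduced-resolution image-to-image translator.

    A fully connected encoder-decoder on downscaled rasters: the
    boundary image (grayscale, normalized) maps to the three main-path
    channels.  Deliberately small so it trains in seconds on a desk
    machine; outputs are post-processed by :func:`postprocess_raster`
    to restore the hard channel invariants before decoding.
    """

    def __init__(
        self,
        resolution: int = 32,
        hidden_layer_sizes: tuple[int, ...] = (256,),
        max_iter: int = 600,
        random_state: int = 0,
        learning_rate_init: float = 2e-3,
    ):
        self.resolution = resolution
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.random_state = random_state
        self.learning_rate_init = learning_rate_init

    def _down(self, img: np.ndarray, channels: int) -> np.ndarray:
        from PIL import Image

        if img.ndim == 2 and channels == 3:
            img = np.stack([img] * 3, axis=-1)
        img = img.astype(np.uint8)
        if channels == 3:
            # dilate sparse channels so single-pixel midpoints survive
            # the downscale; the decoder re-centroids blobs on the way back
            from scipy.ndimage import maximum_filter

            H, W = img.shape[:2]
            size = (
                2 * max(H // self.resolution, 1) + 1,
                2 * max(W // self.resolution, 1) + 1,
            )
            img = np.stack(
                [maximum_filter(img[..., c], size=size) for c in range(3)], axis=-1
            )
        pil = Image.fromarray(img)
        pil = pil.resize((self.resolution, self.resolution), Image.BILINEAR)
        arr = np.asarray(pil, dtype=float) / 255.0
        if channels == 1 and arr.ndim == 2:
            arr = 1.0 - arr  # boundary strokes become the positive signal
        return arr.reshape(-1)

    def fit(self, pairs):
        X = np.array([self._down(s, 1) for s, _ in pairs])
        Y = np.array([self._down(t, 3) for _, t in pairs])
        self.net_ = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate_init,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.net_.fit(X, Y)
        if not np.isfinite(self.net_.loss_):
            raise TrainingError("translator training diverged")
        return self

    def predict_raster(self, boundary_image: np.ndarray, out_shape) -> np.ndarray:
        from PIL import Image

        check_is_fitted(self, "net_")
        x = self._down(boundary_image, 1)[None, :]
        y = self.net_.predict(x)[0].reshape(self.resolution, self.resolution, 3)
        y = np.clip(y * 255.0, 0, 255).astype(np.uint8)
        H, W = out_shape
        return np.asarray(Image.fromarray(y).resize((W, H), Image.BILINEAR))


def postprocess_raster(raw: np.ndarray, l_min: float, l_max: float) -> "MainPathImage":
    """Threshold a translator raster back into valid channel semantics."""
    from skimage.measure import label as sk_label

    from .codec import MainPathImage

    H, W = raw.shape[:2]
    out = np.zeros((H, W, 3), dtype=np.uint8)
    # translator amplitudes are soft; threshold relative to the response
    r_thr = max(64, int(0.5 * raw[..., 0].max()))
    rmask = raw[..., 0] >= r_thr
    out[..., 0] = np.where(rmask, 255, 0)
    # midpoints: one pixel per strong B blob
    b_thr = max(64, int(0.6 * raw[..., 2].max()))
    bmask = (raw[..., 2] >= b_thr) & rmask
    lab, n = sk_label(bmask, connectivity=2, return_num=True)
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        r, c = int(round(ys.mean())), int(round(xs.mean()))
        out[r, c, 2] = 255
        out[r, c, 1] = int(raw[ys, xs, 1].max())
    if n == 0 and bmask.size:
        # salvage: take the three strongest responses inside the region
        b = np.where(rmask, raw[..., 2].astype(int), -1)
        for flat in np.argsort(b.ravel())[-3:]:
            r, c = np.unravel_index(flat, b.shape)
            if b[r, c] > 0:
                out[r, c, 2] = 255
                out[r, c, 1] = int(raw[r, c, 1])
    # boundary: zero the rim of each region (overwrites any channel there)
    from scipy import ndimage as ndi

    rim = rmask & ~ndi.binary_erosion(rmask)
    out[rim] = 0
    return MainPathImage(
        pixels=out,
        l_min=l_min,
        l_max=l_max,
        px_per_unit=1.0,
        origin=(0.0, 0.0),
        mode="model",
    )


def fallback_main_path(
    boundary_image: np.ndarray,
    seed: int = 0,
    band_fraction: float = 0.30,
    spacing_factor: float = 2.2,
) -> "MainPathImage":
    """Deterministic boundary-to-main-path stage.

    The wing area is the filled dark outline; the main-path region is
    an inward-offset strip along its leading (top) edge, midpoints sit
    on a jittered line through the strip with lengths declining from
    front to back.  Same boundary and seed give a bit-identical raster.
    """
    from scipy import ndimage as ndi

    from .codec import MainPathImage

    img = np.asarray(boundary_image)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    mask = img < 128
    if not mask.any():
        raise CodecError("boundary image contains no outline")
    area = ndi.binary_fill_holes(mask)
    H, W = area.shape
    rows_any = np.nonzero(area.any(axis=1))[0]
    band_h = max(6, int(band_fraction * (rows_any[-1] - rows_any[0] + 1) * 0.35))

    # inward offset of the wing area
    inset = ndi.binary_erosion(area, iterations=3)
    top_edge = np.full(W, -1)
    for c in range(W):
        rs = np.nonzero(inset[:, c])[0]
        if len(rs):
            top_edge[c] = rs[0]
    region = np.zeros((H, W), bool)
    for c in range(W):
        if top_edge[c] >= 0:
            region[top_edge[c] : top_edge[c] + band_h, c] = True
    region &= inset
    # clean ragged columns
    region = ndi.binary_opening(region, structure=np.ones((3, 3)))
    if not region.any():
        raise CodecError("offset band is empty; boundary too small")

    out = np.zeros((H, W, 3), dtype=np.uint8)
    out[..., 0] = np.where(region, 255, 0)
    rim = region & ~ndi.binary_erosion(region)
    out[rim] = 0
    interior = region & ~ndi.binary_dilation(rim, iterations=2)
    if not interior.any():
        interior = region

    rng = np.random.default_rng(seed)
    cols_any = np.nonzero(interior.any(axis=0))[0]
    c0, c1 = cols_any[0], cols_any[-1]
    # near-equilateral spacing against the two staggered rows below
    spacing = max(4, int(0.62 * band_h))
    l_max = float(spacing) * 1.8
    l_min = max(1.0, 0.4 * l_max)
    placed = 0
    # two staggered rows of midpoints, so the band triangulates into a
    # proper two-layer strip (the reconstructed dual then has cells)
    mp_tmp = MainPathImage(out, l_min, l_max, 1.0, (0.0, 0.0))
    for row_i, frac in enumerate((0.28, 0.72)):
        xs = np.arange(
            c0 + spacing // 2 + row_i * spacing // 2,
            c1 - spacing // 4 + 1,
            max(spacing, 4),
        )
        for x in xs:
            c = int(np.clip(x + rng.integers(-spacing // 5, spacing // 5 + 1), 0, W - 1))
            rs = np.nonzero(interior[:, c])[0]
            if not len(rs):
                continue
            r = int(np.clip(rs[0] + int(frac * (rs[-1] - rs[0])), 0, H - 1))
            if not interior[r, c]:
                r = int(rs[len(rs) // 2])
            t = (c - c0) / max(c1 - c0, 1)
            length = l_min + (l_max - l_min) * (1.0 - t)
            out[r, c, 2] = 255
            out[r, c, 1] = mp_tmp.quantize(length)
            out[r, c, 0] = 255 if region[r, c] else out[r, c, 0]
            placed += 1
    if placed < 3:
        raise CodecError("could not place at least 3 midpoints in the band")
    return MainPathImage(
        pixels=out, l_min=l_min, l_max=l_max, px_per_unit=1.0, origin=(0.0, 0.0),
        mode="fallback",
    )


def translate_boundary_to_mainpath(
    boundary_image: np.ndarray,
    model: MainPathTranslator | None = None,
    seed: int = 0,
    l_range: tuple[float, float] | None = None,
) -> "MainPathImage":
    """Boundary raster to main-path raster, learned or deterministic.

    With a fitted translator the raw prediction is post-processed to
    restore channel invariants and verified decodable; on failure (or
    with ``model=None``) the deterministic fallback runs instead, with
    a warning in the learned case.  The mode is recorded in metadata.
    """
    from .codec import decode_main_path

    if model is not None:
        l_min, l_max = l_range if l_range else (1.0, 10.0)
        raw = model.predict_raster(boundary_image, np.asarray(boundary_image).shape[:2])
        mp = postprocess_raster(raw, l_min, l_max)
        try:
            decode_main_path(mp, opening=1)
            return mp
        except CodecError:
            warnings.warn("translator output failed to decode; using fallback")
    return fallback_main_path(boundary_image, seed=seed)
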