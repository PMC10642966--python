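"""Quantitative evaluation: Dice, border distances, topology, ablation.

The benchmark compares three conditions on a common cohort: conventional
3D volumetric registration of binarized masks (control), unfolding alone
(intrinsic alignment, identity transforms in unfolded space), and
unfolding followed by multi-channel registration in unfolded space.
Subfield agreement with the reference sample is measured by Dice overlap
(in unfolded and native space), minimum border distances in mm, and
topology checks (connected-component breaks and proximal-distal ordering
violations); condition differences are tested with one-tailed
paired-samples t-tests pairing subfields and subjects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as cc_label

from .control import ControlParams, run_volumetric_condition
from .io import GRAY_LABELS, SUBFIELD_NAMES, DEFAULT_GRID, LabelVolume, UnfoldedMap
from .morphometry import FeatureStack, compute_features, prepare_feature_stack
from .phantom import PhantomSample
from .propagation import project_to_native, propagate_labels_unfolded
from .registration import DiffeoTransform, RegParams, build_template
from .unfolding import (compute_coordinates, extract_midthickness_grid,
                        project_labels_to_unfolded)

DEFAULT_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5))  # Sub-CA1 ... CA3-CA4


# ---------------------------------------------------------------------------
# metrics

def dice_scores(ref: np.ndarray, test: np.ndarray,
                label_ids=GRAY_LABELS) -> dict:
    """Per-label Dice overlap 2|A^B| / (|A|+|B|); NaN when both empty."""
    ref = np.asarray(ref)
    test = np.asarray(test)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    out = {}
    for lab in label_ids:
        a = ref == lab
        b = test == lab
        denom = int(a.sum()) + int(b.sum())
        out[int(lab)] = (np.nan if denom == 0
                         else 2.0 * int((a & b).sum()) / denom)
    return out


def _border_mask(labels: np.ndarray, a: int, b: int) -> np.ndarray:
    """Voxels of label a 6-adjacent to label b (one-sided border band,
    so each interface is represented once)."""
    la = labels == a
    lb = labels == b
    struct = ndimage.generate_binary_structure(labels.ndim, 1)
    return la & ndimage.binary_dilation(lb, structure=struct)


def border_distances(ref: LabelVolume, test: LabelVolume,
                     pairs=DEFAULT_PAIRS, warn: list | None = None) -> dict:
    """Minimum real-world distances between corresponding subfield borders.

    For each pair, a Euclidean distance transform (mm) from the reference
    border is read at the test border's voxels.  Distances are pooled
    across pairs and summarized by the median.
    """
    if ref.voxels.shape != test.voxels.shape:
        raise ValueError("border_distances requires a common grid")
    spacing = ref.spacing
    per_pair = {}
    pooled = []
    for a, b in pairs:
        rb = _border_mask(np.asarray(ref.voxels), a, b)
        tb = _border_mask(np.asarray(test.voxels), a, b)
        if not rb.any():
            if warn is not None:
                warn.append(f"pair ({a},{b}) absent in reference")
            per_pair[(a, b)] = np.array([np.nan])
            continue
        dist = ndimage.distance_transform_edt(~rb, sampling=spacing)
        d = dist[tb] if tb.any() else np.array([np.nan])
        per_pair[(a, b)] = d
        if np.isfinite(d).any():
            pooled.append(d[np.isfinite(d)])
    pooled = np.concatenate(pooled) if pooled else np.array([np.nan])
    return {"per_pair": per_pair, "pooled": pooled,
            "median": float(np.nanmedian(pooled))}


def topology_check(label_map: UnfoldedMap | np.ndarray) -> dict:
    """Count connected-component breaks and P-D ordering violations.

    A subfield split into >1 8-connected components is a break.  Scanning
    each anterior-posterior row along the proximal-distal axis, non-zero
    labels must be non-decreasing in the order Sub < CA1 < CA2 < CA3 <
    CA4; skipped subfields are allowed, reversals are violations.
    """
    vals = np.asarray(label_map.values if isinstance(label_map, UnfoldedMap)
                      else label_map)
    components = {}
    n_breaks = 0
    for lab in GRAY_LABELS:
        m = vals == lab
        if not m.any():
            continue
        _, n = cc_label(m, connectivity=2, return_num=True)
        components[int(lab)] = int(n)
        n_breaks += max(0, n - 1)
    n_order = 0
    for row in vals:
        nz = row[row > 0]
        if nz.size > 1:
            n_order += int((np.diff(nz.astype(int)) < 0).sum())
    return {"components": components, "n_breaks": int(n_breaks),
            "n_order_violations": int(n_order)}


def paired_one_tailed_t(a, b) -> dict:
    """One-tailed paired t-test (alternative: mean(a) > mean(b))."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    n = d.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return {"t": 0.0, "p": 0.5, "n": n, "degenerate": True}
        t = np.inf if d.mean() > 0 else -np.inf
        return {"t": float(t), "p": 0.0 if t > 0 else 1.0, "n": n,
                "degenerate": True}
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return {"t": float(t), "p": p, "n": n, "degenerate": False}


# ---------------------------------------------------------------------------
# per-sample preparation

@dataclass
class SamplePrep:
    """Unfolding products of one sample, reused across conditions."""

    coords: object
    grid: object
    unfolded_labels: UnfoldedMap
    stack: FeatureStack


def _subfields_only(vol: LabelVolume) -> LabelVolume:
    v = np.asarray(vol.voxels)
    return LabelVolume(np.where((v >= 1) & (v <= 5), v, 0).astype(np.int16),
                       np.asarray(vol.affine))


def prepare_sample(vol: LabelVolume, grid_shape=DEFAULT_GRID,
                   tol: float = 1e-5, sigma_mm: float = 1.0) -> SamplePrep:
    """Unfold one sample and compute its unfolded labels and features."""
    coords = compute_coordinates(vol, tol=tol)
    grid = extract_midthickness_grid(coords, vol, shape=grid_shape)
    labels = project_labels_to_unfolded(_subfields_only(vol), coords,
                                        shape=grid_shape)
    feats = compute_features(coords, grid, sigma_mm=sigma_mm)
    stack = prepare_feature_stack(feats)
    # extrapolated grid nodes carry no real measurement either
    stack.valid = (stack.valid & grid.valid if stack.valid is not None
                   else grid.valid)
    return SamplePrep(coords=coords, grid=grid, unfolded_labels=labels,
                      stack=stack)


# ---------------------------------------------------------------------------
# ablation

ALL_FEATURES = ("thickness", "gyrification", "curvature")


def feature_subsets(features=ALL_FEATURES) -> list[tuple[str, ...]]:
    return [c for r in range(1, len(features) + 1)
            for c in itertools.combinations(features, r)]


def feature_ablation(preps: list[SamplePrep], ref_vol: LabelVolume,
                     ref_index: int = 0, subsets=None,
                     reg_params: RegParams | None = None,
                     n_iter: int = 4) -> pd.DataFrame:
    """Re-run unfolded registration for every feature subset.

    Each subset builds its own template and propagates subfield labels to
    the reference; performance is the native-space Dice averaged over
    subfields and samples.  The table is sorted by mean Dice, best first.
    """
    subsets = subsets or feature_subsets()
    ref_sub = _subfields_only(ref_vol)
    rows = []
    for subset in subsets:
        stacks = [p.stack.subset(list(subset)) for p in preps]
        tmpl = build_template(stacks, n_iter=n_iter, params=reg_params)
        scores = []
        for i, p in enumerate(preps):
            if i == ref_index:
                continue
            prop = propagate_labels_unfolded(p.unfolded_labels,
                                             tmpl.transforms[i],
                                             tmpl.transforms[ref_index])
            native, _ = project_to_native(preps[ref_index].coords, prop,
                                          ref_vol)
            d = dice_scores(ref_sub.voxels, native.voxels)
            scores.extend(v for v in d.values() if np.isfinite(v))
        rows.append({"features": "+".join(subset),
                     "n_features": len(subset),
                     "mean_dice": float(np.mean(scores))})
    df = pd.DataFrame(rows).sort_values("mean_dice", ascending=False)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# benchmark

CONDITIONS = ("volumetric", "unfold_only", "unfolded_reg")


@dataclass
class EvaluationReport:
    dice: pd.DataFrame  # condition, sample, subfield, space, dice
    border: dict  # condition -> {"median": float, "per_sample_median": {...}}
    topology: pd.DataFrame  # condition, sample, n_breaks, n_order_violations
    tests: dict  # comparison -> {space -> t-test dict}
    ablation: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def mean_dice(self, condition: str, space: str = "native") -> float:
        df = self.dice
        sel = df[(df.condition == condition) & (df.space == space)]
        return float(sel.dice.mean())

    def subfield_means(self, condition: str, space: str = "native"):
        df = self.dice
        sel = df[(df.condition == condition) & (df.space == space)]
        return sel.groupby("subfield").dice.mean()

    def to_dict(self) -> dict:
        out = {"mean_dice": {}, "border_median_mm": {}, "topology": {},
               "tests": self.tests, "meta": self.meta}
        for cond in CONDITIONS:
            out["mean_dice"][cond] = {
                sp: self.mean_dice(cond, sp) for sp in ("unfolded", "native")}
            out["border_median_mm"][cond] = self.border[cond]["median"]
            sub = self.topology[self.topology.condition == cond]
            out["topology"][cond] = {
                "n_breaks": int(sub.n_breaks.sum()),
                "n_order_violations": int(sub.n_order_violations.sum())}
        if self.ablation is not None:
            out["ablation"] = {r.features: r.mean_dice
                               for r in self.ablation.itertuples()}
        return out


def run_benchmark(samples: list[PhantomSample], ref_index: int = 0,
                  grid_shape=DEFAULT_GRID,
                  reg_params: RegParams | None = None,
                  control_params: ControlParams | None = None,
                  n_template_iter: int = 4,
                  with_ablation: bool = False,
                  tol: float = 1e-5) -> EvaluationReport:
    """Run all three conditions on a cohort and evaluate them.

    ``samples`` come from the phantom cohort generator (or any source
    providing labelmaps with hemisphere metadata).  The unfolding-only
    condition is exactly the registered condition with identity
    transforms.  Everything downstream of the cohort is deterministic.
    """
    vols = [s.labels for s in samples]
    hemis = [s.params.hemisphere for s in samples]
    preps = [prepare_sample(v, grid_shape=grid_shape, tol=tol) for v in vols]
    ref_vol = vols[ref_index]
    ref_prep = preps[ref_index]
    ref_sub = _subfields_only(ref_vol)
    ref_unfolded = ref_prep.unfolded_labels

    # condition: unfolded registration (groupwise template of feature stacks)
    tmpl = build_template([p.stack for p in preps], n_iter=n_template_iter,
                          params=reg_params)
    identity = DiffeoTransform.identity(tuple(grid_shape))

    # condition: volumetric control
    cparams = control_params or ControlParams(ref_index=ref_index)
    cparams.ref_index = ref_index
    ctrl = run_volumetric_condition(vols, cparams, hemispheres=hemis,
                                    ref_grid=ref_prep.grid)

    dice_rows = []
    topo_rows = []
    border = {c: {"pooled": [], "per_sample_median": {}} for c in CONDITIONS}

    for i, p in enumerate(preps):
        if i == ref_index:
            continue
        per_cond = {}
        # unfold-only: identity transforms in unfolded space
        unf = propagate_labels_unfolded(p.unfolded_labels, identity, identity)
        nat, _ = project_to_native(ref_prep.coords, unf, ref_vol)
        per_cond["unfold_only"] = (unf, nat)
        # unfolded registration
        reg = propagate_labels_unfolded(p.unfolded_labels, tmpl.transforms[i],
                                        tmpl.transforms[ref_index])
        natr, _ = project_to_native(ref_prep.coords, reg, ref_vol)
        per_cond["unfolded_reg"] = (reg, natr)
        # volumetric control
        cres = ctrl.results[i]
        per_cond["volumetric"] = (cres.unfolded, cres.native)

        for cond, (unf_map, nat_vol) in per_cond.items():
            d2 = dice_scores(ref_unfolded.values, unf_map.values)
            d3 = dice_scores(ref_sub.voxels, nat_vol.voxels)
            for lab in GRAY_LABELS:
                dice_rows.append({"condition": cond, "sample": i,
                                  "subfield": SUBFIELD_NAMES[lab],
                                  "space": "unfolded", "dice": d2[lab]})
                dice_rows.append({"condition": cond, "sample": i,
                                  "subfield": SUBFIELD_NAMES[lab],
                                  "space": "native", "dice": d3[lab]})
            topo = topology_check(unf_map)
            topo_rows.append({"condition": cond, "sample": i,
                              "n_breaks": topo["n_breaks"],
                              "n_order_violations":
                                  topo["n_order_violations"]})
            bd = border_distances(ref_sub, nat_vol)
            border[cond]["pooled"].append(bd["pooled"])
            border[cond]["per_sample_median"][i] = float(
                np.nanmedian(bd["pooled"]))

    dice = pd.DataFrame(dice_rows)
    topology = pd.DataFrame(topo_rows)
    for cond in CONDITIONS:
        pooled = np.concatenate(border[cond].pop("pooled"))
        border[cond]["median"] = float(np.nanmedian(pooled))

    tests = {}
    pairs = [("unfolded_reg", "unfold_only"),
             ("unfold_only", "volumetric"),
             ("unfolded_reg", "volumetric")]
    for ca, cb in pairs:
        tests[f"{ca}_gt_{cb}"] = {}
        for space in ("unfolded", "native"):
            va = _dice_vector(dice, ca, space)
            vb = _dice_vector(dice, cb, space)
            tests[f"{ca}_gt_{cb}"][space] = paired_one_tailed_t(va, vb)

    ablation = None
    if with_ablation:
        ablation = feature_ablation(preps, ref_vol, ref_index=ref_index,
                                    reg_params=reg_params,
                                    n_iter=n_template_iter)

    meta = {"n_samples": len(samples), "ref_index": ref_index,
            "grid_shape": list(grid_shape),
            "hemispheres": hemis}
    return EvaluationReport(dice=dice, border=border, topology=topology,
                            tests=tests, ablation=ablation, meta=meta)


def _dice_vector(df: pd.DataFrame, condition: str, space: str) -> np.ndarray:
    sel = df[(df.condition == condition) & (df.space == space)]
    sel = sel.sort_values(["sample", "subfield"])
    return np.nan_to_num(sel.dice.to_numpy(), nan=0.0)
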