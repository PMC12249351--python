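"""Physics and labeling checks for the radiograph generator."""

import math

import numpy as np
import pytest

from wknet.synthetic_xray import (
    BeamConfig,
    LabeledImage,
    WalnutPhantom,
    add_conveyor_speckle,
    generate_dataset,
    make_scene,
    optical_depth,
    path_lengths,
    phantom_box,
    render_attenuation,
    transmitted_intensity,
)


# ---------------------------------------------------------------------------
# ray-marching oracle (independent of the analytic chord formulas)


def raymarch_lengths(p: WalnutPhantom, px, py, step_mm=0.01):
    """Numeric 10-um ray marching through the explicit 3-D solids."""
    dx = (px - p.center[0]) * p.mm_per_pixel
    dy = (py - p.center[1]) * p.mm_per_pixel
    co, si = math.cos(p.orientation), math.sin(p.orientation)
    u = co * dx + si * dy
    v = -si * dx + co * dy
    a, b = p.shell_semi_axes
    c = p.depth_semi_axis
    ca, cb, cc = a - p.shell_thickness, b - p.shell_thickness, c - p.shell_thickness
    off, (la, lb, lc) = p.lobe_geometry()
    zs = np.arange(-c, c, step_mm) + step_mm / 2
    inside = lambda x, y, z, A, B, C: (x / A) ** 2 + (y / B) ** 2 + (z / C) ** 2 <= 1
    outer = inside(u, v, zs, a, b, c)
    cavity = inside(u, v, zs, ca, cb, cc)
    shell = outer & ~cavity
    septum = cavity & (abs(u) <= p.septum_thickness / 2)
    kernel = np.zeros_like(outer)
    if p.kernel_fill_fraction > 0 and min(la, lb, lc) > 0:
        kernel = inside(u - off, v, zs, la, lb, lc) | inside(u + off, v, zs, la, lb, lc)
    return {
        "shell": shell.sum() * step_mm,
        "kernel": kernel.sum() * step_mm,
        "septum": septum.sum() * step_mm,
    }


def test_path_lengths_outside_silhouette_are_zero(centered_phantom):
    L = path_lengths(centered_phantom, (0.0, 0.0))  # far corner
    assert all(float(v) == 0.0 for v in L.values())


def test_path_lengths_match_raymarch_oracle(centered_phantom):
    p = centered_phantom
    rng = np.random.default_rng(5)
    hw, hh = p.half_extents_px()
    pts = [
        (p.center[0], p.center[1]),
        (p.center[0] + 0.5 * hw, p.center[1]),
        (p.center[0], p.center[1] - 0.6 * hh),
    ] + [
        (p.center[0] + rng.uniform(-hw, hw), p.center[1] + rng.uniform(-hh, hh))
        for _ in range(12)
    ]
    for px, py in pts:
        analytic = path_lengths(p, (px, py))
        marched = raymarch_lengths(p, px, py)
        for mat in ("shell", "kernel", "septum"):
            assert abs(float(analytic[mat]) - marched[mat]) < 0.05, (
                f"{mat} at ({px:.1f},{py:.1f}): "
                f"{float(analytic[mat]):.4f} vs {marched[mat]:.4f}"
            )


def test_kernel_chord_of_spherical_lobe_is_fill_adjusted_diameter():
    # sphere-like phantom, ray through a lobe center
    p = WalnutPhantom(
        quality_class="accept", center=(50.0, 50.0),
        shell_semi_axes=(16.0, 16.0), shell_thickness=1.0,
        kernel_fill_fraction=1.0, orientation=0.0, mm_per_pixel=0.5,
    )
    off, (la, lb, lc) = p.lobe_geometry()
    px = 50.0 + off / p.mm_per_pixel
    L = path_lengths(p, (px, 50.0))
    assert abs(float(L["kernel"]) - 2 * lc) < 1e-9
    marched = raymarch_lengths(p, px, 50.0)
    assert abs(marched["kernel"] - 2 * lc) < 0.05


def test_total_chord_is_maximal_near_center_and_decreases_to_rim(centered_phantom):
    p = centered_phantom
    hw, _ = p.half_extents_px()
    xs = np.linspace(p.center[0], p.center[0] + hw * 1.05, 40)
    # the outer-ellipsoid chord profile must be monotone decreasing to the rim
    from wknet.synthetic_xray import _ellipsoid_chord

    a, b = p.shell_semi_axes
    chord = _ellipsoid_chord(
        (xs - p.center[0]) * p.mm_per_pixel * math.cos(p.orientation),
        (xs - p.center[0]) * p.mm_per_pixel * math.sin(p.orientation),
        a, b, p.depth_semi_axis,
    )
    assert chord[0] == chord.max()
    assert np.all(np.diff(chord) <= 1e-9)
    assert chord[-1] == 0.0


# ---------------------------------------------------------------------------
# Beer-Lambert rendering


def test_render_zero_attenuation_gives_gain_times_i0(quiet_beam):
    # mu*L = 0 everywhere outside the silhouette: background == gain * I0
    img = transmitted_intensity([], quiet_beam, canvas=(40, 30))
    np.testing.assert_allclose(img, 230.0)


def test_half_value_layer(centered_phantom, quiet_beam):
    """A ray with total optical depth ln 2 transmits exactly I0/2."""
    p = centered_phantom
    L = path_lengths(p, (p.center[0], p.center[1]))
    total = (
        p.mu_shell * float(L["shell"])
        + p.mu_kernel * float(L["kernel"])
        + p.mu_septum * float(L["septum"])
    )
    scale = math.log(2.0) / total
    q = WalnutPhantom(**{**p.to_dict(),
                         "mu_shell": p.mu_shell * scale,
                         "mu_kernel": p.mu_kernel * scale,
                         "mu_septum": p.mu_septum * scale})
    img = transmitted_intensity([q], quiet_beam, canvas=(220, 170))
    cy, cx = int(p.center[1]), int(p.center[0])
    incident = quiet_beam.detector_gain * quiet_beam.source_intensity
    assert abs(img[cy, cx] / incident - 0.5) < 1e-9


def test_beer_lambert_composability(centered_phantom, quiet_beam):
    """Stacked materials equal one material with the summed mu*L."""
    p = centered_phantom
    tau = optical_depth([p], canvas=(220, 170))
    gy, gx = np.mgrid[0:170, 0:220]
    L = path_lengths(p, (gx, gy))
    tau_manual = (
        p.mu_shell * L["shell"] + p.mu_kernel * L["kernel"] + p.mu_septum * L["septum"]
    )
    trans = np.exp(-tau)
    per_material = (
        np.exp(-p.mu_shell * L["shell"])
        * np.exp(-p.mu_kernel * L["kernel"])
        * np.exp(-p.mu_septum * L["septum"])
    )
    np.testing.assert_allclose(tau, tau_manual, rtol=1e-12, atol=1e-12)
    mask = trans > 0
    assert np.max(np.abs(trans - per_material)[mask] / trans[mask]) < 1e-9


def test_transmission_ratio_in_unit_interval(centered_phantom, quiet_beam):
    img = transmitted_intensity([centered_phantom], quiet_beam, canvas=(220, 170))
    ratio = img / (quiet_beam.detector_gain * quiet_beam.source_intensity)
    assert np.all(ratio > 0) and np.all(ratio <= 1.0)


def test_intensity_monotone_in_attenuation(centered_phantom, quiet_beam):
    p = centered_phantom
    stronger = WalnutPhantom(**{**p.to_dict(), "mu_kernel": p.mu_kernel * 2})
    a = transmitted_intensity([p], quiet_beam, canvas=(220, 170))
    b = transmitted_intensity([stronger], quiet_beam, canvas=(220, 170))
    assert np.all(b <= a + 1e-12)


def test_render_boxes_enclose_dark_pixels(tiny_scene):
    img, _ = tiny_scene
    h, w = img.shape
    vals, counts = np.unique(img.pixels, return_counts=True)
    bg_mode = int(vals[counts.argmax()])
    for _, xc, yc, bw, bh in img.boxes:
        x0, x1 = int((xc - bw / 2) * w), int((xc + bw / 2) * w)
        y0, y1 = int((yc - bh / 2) * h), int((yc + bh / 2) * h)
        assert int(img.pixels[y0:y1, x0:x1].min()) <= bg_mode - 10


def test_overlapping_phantoms_rejected(quiet_beam):
    p1 = WalnutPhantom(center=(60.0, 60.0))
    p2 = WalnutPhantom(center=(70.0, 60.0))
    with pytest.raises(ValueError):
        render_attenuation([p1, p2], quiet_beam, canvas=(200, 150))


def test_phantom_invariant_validation():
    with pytest.raises(ValueError):
        WalnutPhantom(quality_class="accept", kernel_fill_fraction=0.5)
    with pytest.raises(ValueError):
        WalnutPhantom(quality_class="defect", defect_mode="empty_shell",
                      kernel_fill_fraction=0.3)
    with pytest.raises(ValueError):
        WalnutPhantom(mu_shell=-1.0, quality_class="defect",
                      defect_mode="shriveled", kernel_fill_fraction=0.3)


# ---------------------------------------------------------------------------
# speckle


def _blank(w=300, h=200, gray=230):
    return LabeledImage(np.full((h, w), gray, np.uint8), [], "blank")


def test_speckle_density_zero_is_identity():
    img = _blank()
    out = add_conveyor_speckle(img, 0.0, rng_seed=3)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_speckle_deterministic_and_boxes_unchanged(tiny_scene):
    img, _ = tiny_scene
    a = add_conveyor_speckle(img, 0.004, rng_seed=9)
    b = add_conveyor_speckle(img, 0.004, rng_seed=9)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    assert a.boxes == img.boxes


def test_speckle_count_within_binomial_bounds():
    d = 0.001
    img = _blank(400, 300)
    out = add_conveyor_speckle(img, d, rng_seed=1)
    from skimage import measure

    n_components = int(measure.label(out.pixels != 230, connectivity=2).max())
    n_px = 400 * 300
    expect = d * n_px
    sigma = math.sqrt(n_px * d * (1 - d))
    assert abs(n_components - expect) < 4 * sigma


def test_speckle_density_bound_enforced():
    with pytest.raises(ValueError):
        add_conveyor_speckle(_blank(), 0.2)


# ---------------------------------------------------------------------------
# dataset generation


def test_generate_dataset_counts_and_classes(tmp_path):
    manifest = generate_dataset(
        10, 5, (1.0, 0.0), seed=4, out_dir=tmp_path, canvas=(400, 320),
    )
    pngs = sorted((tmp_path / "images").glob("*.png"))
    txts = sorted((tmp_path / "labels").glob("*.txt"))
    assert len(pngs) == 10 and len(txts) == 10
    total = 0
    for t in txts:
        lines = [ln for ln in t.read_text().splitlines() if ln.strip()]
        total += len(lines)
        assert all(ln.split()[0] == "0" for ln in lines)  # accept-only mix
    assert total == 50
    assert len(manifest["images"]) == 10


def test_generate_dataset_deterministic(tmp_path):
    m1 = generate_dataset(3, 3, (0.5, 0.5), seed=9, out_dir=tmp_path / "a",
                          canvas=(400, 320))
    m2 = generate_dataset(3, 3, (0.5, 0.5), seed=9, out_dir=tmp_path / "b",
                          canvas=(400, 320))
    for k in m1["images"]:
        pa = (tmp_path / "a" / "images" / f"{k}.png").read_bytes()
        pb = (tmp_path / "b" / "images" / f"{k}.png").read_bytes()
        assert pa == pb
        la = (tmp_path / "a" / "labels" / f"{k}.txt").read_text()
        lb = (tmp_path / "b" / "labels" / f"{k}.txt").read_text()
        assert la == lb


def test_class_mix_must_sum_to_one(tmp_path):
    with pytest.raises(ValueError):
        generate_dataset(2, 2, (0.7, 0.6), seed=0, out_dir=tmp_path)
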