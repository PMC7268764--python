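"""Independent closed-form oracles for circle-arc / line-segment scenes.

The scenes pair a circular-arc corneoscleral wall (radius R, apex at the
origin, centre at (0, R)) with a piecewise-linear iris: either a single
segment from the pupil margin to a root on the wall, or a two-segment "tent"
whose middle vertex models the bombé summit.  Everything here is computed
with explicit line/circle algebra and dense shoelace sampling — no code from
the package under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def wall_xy(phi, R):
    phi = np.asarray(phi, dtype=float)
    return np.stack([R * np.sin(phi), R * (1.0 - np.cos(phi))], axis=-1)


def phi_of_depth(y, R):
    return math.acos(1.0 - y / R)


@dataclass
class ArcScene:
    """Circle-arc wall + polyline iris with exact reference solutions."""

    R: float
    phi_spur: float
    iris: np.ndarray          # (2 or 3, 2); last vertex lies on the circle
    phi_max: float

    # -- exact constructions ------------------------------------------------

    @property
    def spur(self) -> np.ndarray:
        return wall_xy(self.phi_spur, self.R)

    def wall_point(self, offset: float):
        phi = self.phi_spur - offset / self.R
        w = wall_xy(phi, self.R)
        normal_in = (np.array([0.0, self.R]) - w) / self.R
        return phi, w, normal_in

    def aod(self, offset: float):
        """(distance, hit point, segment index, u) of the perpendicular cast."""
        _, w, n = self.wall_point(offset)
        best = None
        for i in range(len(self.iris) - 1):
            a, b = self.iris[i], self.iris[i + 1]
            v = b - a
            den = n[0] * v[1] - n[1] * v[0]
            if abs(den) < 1e-14:
                continue
            wv = a - w
            t = (wv[0] * v[1] - wv[1] * v[0]) / den
            u = (wv[0] * n[1] - wv[1] * n[0]) / den
            if 0.0 <= u <= 1.0 and t >= 0 and (best is None or t < best[0]):
                best = (t, a + u * v, i, u)
        if best is None:
            raise RuntimeError("oracle: AOD cast misses the iris")
        return best

    def tisa750(self, arc_step: float = 1e-4) -> float:
        d0, i0, seg0, u0 = self.aod(0.0)
        d1, i1, seg1, u1 = self.aod(0.75)
        phi_ant = self.phi_spur - 0.75 / self.R
        n = max(8, int(math.ceil(0.75 / arc_step)))
        phis = np.linspace(phi_ant, self.phi_spur, n)
        arc = wall_xy(phis, self.R)
        # iris vertices strictly between the two hits (walking i0 -> i1,
        # i.e. from the spur-side hit toward the anterior hit)
        inner = []
        for k in range(len(self.iris)):
            pos = (k, 0.0)
            lo, hi = sorted([(seg1, u1), (seg0, u0)])
            if lo < pos < hi:
                inner.append(self.iris[k])
        inner = inner[::-1]  # descending, i0-side first
        pts = [arc[0], *arc[1:-1], arc[-1], i0, *inner, i1]
        poly = np.array(pts)
        x, y = poly[:, 0], poly[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1))
                               - np.dot(np.roll(x, -1), y)))

    def supporting_vertex(self):
        th = np.arctan2(self.iris[:, 1], self.iris[:, 0])
        return int(np.argmin(th))

    def lid(self):
        """Signed LID from the apex-supporting line (None when off the arc)."""
        k = self.supporting_vertex()
        v = self.iris[k]
        theta = math.atan2(v[1], v[0])
        phi_x = 2.0 * theta          # inscribed-angle: ray at polar angle
        if phi_x > self.phi_max + 1e-12:
            return None
        u = v / np.linalg.norm(v)
        s = 2.0 * u[1] * self.R      # u . centre with centre = (0, R)
        x_pt = s * u
        mag = float(np.linalg.norm(x_pt - self.spur))
        if abs(phi_x - self.phi_spur) < 1e-14:
            return 0.0
        return mag if phi_x > self.phi_spur else -mag

    # -- discretization for the code under test ----------------------------

    def wall_polyline(self, spacing: float = 0.003) -> np.ndarray:
        n = max(3, int(math.ceil(self.phi_max * self.R / spacing)) + 1)
        return wall_xy(np.linspace(0.0, self.phi_max, n), self.R)

    def iris_polyline(self, spacing: float = 0.003) -> np.ndarray:
        pts = [self.iris[0]]
        for i in range(len(self.iris) - 1):
            a, b = self.iris[i], self.iris[i + 1]
            n = max(2, int(math.ceil(np.linalg.norm(b - a) / spacing)) + 1)
            seg = a[None, :] + np.linspace(0, 1, n)[1:, None] * (b - a)[None, :]
            pts.extend(seg)
        return np.array(pts)

    def build_section(self, spacing: float = 0.003):
        from acangle.geometry import BScanSection

        return BScanSection(posterior_cornea=self.wall_polyline(spacing),
                            anterior_iris=self.iris_polyline(spacing),
                            scleral_spur=self.spur, side="right")


def random_scene(rng: np.random.Generator, tent: bool = True) -> ArcScene:
    """Draw a feasible random scene (rejection sampling, deterministic)."""
    for _ in range(500):
        R = rng.uniform(6.0, 7.0)
        y_s = rng.uniform(2.6, 3.3)
        phi_s = phi_of_depth(y_s, R)
        phi_root = phi_s + rng.uniform(0.15, 0.45) / R
        root = wall_xy(phi_root, R)
        p0 = np.array([rng.uniform(1.2, 2.2),
                       root[1] - rng.uniform(0.2, 0.6)])
        if tent:
            # place the bombe summit just anterior of the apex-root ray so it
            # is the supporting vertex by construction (margin delta)
            t = rng.uniform(0.35, 0.65)
            x_sum = p0[0] + t * (root[0] - p0[0])
            theta_root = math.atan2(root[1], root[0])
            delta = rng.uniform(0.01, 0.12)
            y_sum = x_sum * math.tan(theta_root - delta)
            iris = np.array([p0, [x_sum, y_sum], root])
        else:
            iris = np.array([p0, root])
        phi_max = min(phi_root + 0.5 / R, 0.98 * math.pi / 2)
        scene = ArcScene(R=R, phi_spur=phi_s, iris=iris, phi_max=phi_max)
        if _feasible(scene, tent):
            return scene
    raise RuntimeError("could not draw a feasible scene")


def _feasible(scene: ArcScene, tent: bool) -> bool:
    R, iris = scene.R, scene.iris
    centre = np.array([0.0, R])
    # interior vertices strictly inside the chamber
    for v in iris[:-1]:
        if np.linalg.norm(v - centre) > R - 0.05 or v[1] < 0.5:
            return False
    if np.any(np.diff(iris[:, 0]) < 0.05):
        return False
    th = np.arctan2(iris[:, 1], iris[:, 0])
    order = np.argsort(th)
    want = 1 if tent else len(iris) - 1      # summit / root must support
    if order[0] != want or th[order[1]] - th[order[0]] < 2e-3:
        return False
    if scene.phi_spur - 0.75 / R < 0.05:
        return False
    try:
        for off in (0.0, 0.75):
            t, _, _, u = scene.aod(off)
            if not (0.03 <= u <= 0.97 and 0.02 <= t <= 1.2):
                return False
    except RuntimeError:
        return False
    lid = scene.lid()
    if lid is None or abs(lid) > 1.2:
        return False
    phi_x = 2.0 * math.atan2(iris[scene.supporting_vertex()][1],
                             iris[scene.supporting_vertex()][0])
    if not (0.05 < phi_x < scene.phi_max - 0.03):
        return False
    return True
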