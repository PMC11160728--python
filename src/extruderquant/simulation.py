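"""Stochastic 1D two-species loop-extrusion simulator.

Implements the double-hierarchical loop picture of interphase genome
re-assembly: a sparse, slow-exchanging Cohesin-STAG1-like species and a
dense, fast-exchanging Cohesin-STAG2-like species extrude loops on a 1D
lattice of 1-kb sites, with CTCF boundary stalling at oriented sites,
mutual blocking on encounter (arms never cross, so loop intervals stay
nested or disjoint), optional pairing on encounter, and stochastic
loading/unloading.

Dynamics use a fixed timestep: per step each species loads
Poisson(loading_rate * lattice_mb * dt) new extruders at random unoccupied
sites, every unstalled arm advances one site with probability
(speed/2) * dt (``speed`` is the TOTAL loop-growth rate, split across the
two arms), and each extruder unloads with probability koff * dt, recording
its completed loop size.  In the sparse, boundary-free limit the mean
completed loop size is speed / koff and the steady-state density is
loading_rate / koff per Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import DistanceMatrix


@dataclass
class SpeciesParams:
    name: str
    loading_rate: float          # events per Mb per second
    koff: float                  # 1/s
    speed: float                 # kb/s total loop growth (both arms)
    ctcf_stall_prob: float = 0.0
    pair_on_encounter: bool = False

    def __post_init__(self) -> None:
        if min(self.loading_rate, self.koff, self.speed) < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.ctcf_stall_prob <= 1.0:
            raise ValueError("ctcf_stall_prob must be in [0, 1]")


@dataclass
class CtcfSite:
    position: float              # kb
    orientation: str             # '+' stalls left-moving arms, '-' right-moving

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass
class ExtruderState:
    id: int
    species: str
    left_anchor: float           # kb
    right_anchor: float          # kb
    left_stalled: bool = False
    right_stalled: bool = False
    paired_with: int | None = None
    load_time: float = 0.0


@dataclass
class SimResult:
    times: np.ndarray                    # density sampling times (s)
    density: np.ndarray                  # (n_samples, n_species) per Mb
    species_names: list
    loop_sizes: np.ndarray               # completed loop sizes (kb)
    loop_species: np.ndarray             # species index per completed loop
    paired_fraction: float
    nesting_depths: np.ndarray           # depth per surviving loop
    final_states: list
    seed: int

    def loop_sizes_for(self, name: str) -> np.ndarray:
        k = self.species_names.index(name)
        return self.loop_sizes[self.loop_species == k]

    def steady_state_density(self, name: str, discard_frac: float = 0.5) -> float:
        k = self.species_names.index(name)
        start = int(len(self.times) * discard_frac)
        return float(np.mean(self.density[start:, k]))


def simulate(lattice_mb: float, species: list, ctcf_sites: list | None = None,
             duration: float = 1000.0, dt: float = 0.1, seed: int = 0,
             record_every: float = 10.0, site_kb: float = 1.0,
             check_invariants: bool = False) -> SimResult:
    """Run the fixed-timestep two-arm loop-extrusion dynamics.

    Anchors live on an integer lattice of ``site_kb``-sized sites; at most
    one anchor per site.  Movement is blocked by the pre-step occupancy and
    simultaneous claims to a site are resolved in favour of the
    lowest-id extruder, which makes anchor crossing impossible and keeps
    all loop intervals nested or disjoint at every step.
    """
    if ctcf_sites is None:
        ctcf_sites = []
    if not species:
        raise ValueError("need at least one species")
    max_speed = max(s.speed for s in species)
    if dt * max_speed > site_kb:
        raise ValueError("stability violation: dt * max(speed) must be <= one site")
    if lattice_mb <= 0 or duration <= 0 or dt <= 0:
        raise ValueError("lattice_mb, duration and dt must be positive")

    rng = np.random.default_rng(seed)
    n_sites = int(round(lattice_mb * 1000.0 / site_kb))
    occ = np.full(n_sites, -1, dtype=np.int64)

    block_left = np.zeros(n_sites, dtype=bool)    # '+' sites stall left arms
    block_right = np.zeros(n_sites, dtype=bool)   # '-' sites stall right arms
    for site in ctcf_sites:
        pos = int(round(site.position / site_kb))
        if not 0 <= pos < n_sites:
            raise ValueError("CTCF site outside the lattice")
        (block_left if site.orientation == "+" else block_right)[pos] = True
    has_ctcf = len(ctcf_sites) > 0

    n_species = len(species)
    p_arm = np.array([s.speed / 2.0 * dt / site_kb for s in species])
    koff_dt = np.array([s.koff * dt for s in species])
    load_lam = np.array([s.loading_rate * lattice_mb * dt for s in species])
    stall_p = np.array([s.ctcf_stall_prob for s in species])
    pair_flag = np.array([s.pair_on_encounter for s in species])

    cap = 1024
    L = np.zeros(cap, dtype=np.int64)
    R = np.zeros(cap, dtype=np.int64)
    spec = np.zeros(cap, dtype=np.int64)
    l_stall = np.zeros(cap, dtype=bool)
    r_stall = np.zeros(cap, dtype=bool)
    paired = np.full(cap, -1, dtype=np.int64)
    t_load = np.zeros(cap, dtype=float)
    alive = np.zeros(cap, dtype=bool)
    n_ext = 0

    loop_sizes: list[float] = []
    loop_spec: list[int] = []
    rec_times: list[float] = []
    rec_density: list[np.ndarray] = []

    def _extend(arr: np.ndarray, fill) -> np.ndarray:
        new = np.full(cap, fill, dtype=arr.dtype)
        new[: arr.size] = arr
        return new

    def _grow(need: int):
        nonlocal cap, L, R, spec, l_stall, r_stall, paired, t_load, alive
        while cap < need:
            cap *= 2
        L, R, spec = _extend(L, 0), _extend(R, 0), _extend(spec, 0)
        l_stall, r_stall = _extend(l_stall, False), _extend(r_stall, False)
        paired, t_load = _extend(paired, -1), _extend(t_load, 0.0)
        alive = _extend(alive, False)

    n_steps = int(round(duration / dt))
    record_steps = max(1, int(round(record_every / dt)))

    for step in range(n_steps):
        t = step * dt

        # --- loading -----------------------------------------------------
        n_new_per_sp = rng.poisson(load_lam)
        total_new = int(n_new_per_sp.sum())
        if total_new:
            if n_ext + total_new > cap:
                _grow(n_ext + total_new)
            for si in range(n_species):
                for _ in range(n_new_per_sp[si]):
                    site = int(rng.integers(n_sites))
                    if occ[site] != -1:
                        continue  # site occupied; attempt lost
                    k = n_ext
                    L[k] = R[k] = site
                    spec[k] = si
                    l_stall[k] = r_stall[k] = False
                    paired[k] = -1
                    t_load[k] = t
                    alive[k] = True
                    occ[site] = k
                    n_ext += 1

        # --- movement ----------------------------------------------------
        idx = np.flatnonzero(alive[:n_ext])
        if idx.size:
            p = p_arm[spec[idx]]
            u = rng.random((idx.size, 2))

            l_try = (~l_stall[idx]) & (L[idx] > 0) & (u[:, 0] < p)
            l_mov = idx[l_try]
            l_tgt = L[l_mov] - 1
            l_occ = occ[l_tgt]
            l_blk = l_occ >= 0
            _register_pairs(paired, pair_flag, spec, l_mov[l_blk], l_occ[l_blk])
            l_mov, l_tgt = l_mov[~l_blk], l_tgt[~l_blk]

            r_try = (~r_stall[idx]) & (R[idx] < n_sites - 1) & (u[:, 1] < p)
            r_mov = idx[r_try]
            r_tgt = R[r_mov] + 1
            r_occ = occ[r_tgt]
            r_blk = r_occ >= 0
            _register_pairs(paired, pair_flag, spec, r_mov[r_blk], r_occ[r_blk])
            r_mov, r_tgt = r_mov[~r_blk], r_tgt[~r_blk]

            # simultaneous claims to one site: lowest id wins
            if l_mov.size and r_mov.size:
                all_tgt = np.concatenate([l_tgt, r_tgt])
                all_slot = np.concatenate([l_mov, r_mov])
                arm = np.concatenate([np.zeros(l_mov.size, dtype=bool),
                                      np.ones(r_mov.size, dtype=bool)])
                order = np.lexsort((all_slot, all_tgt))
                first = np.ones(order.size, dtype=bool)
                st = all_tgt[order]
                first[1:] = st[1:] != st[:-1]
                win = order[first]
                l_sel = win[~arm[win]]
                r_sel = win[arm[win]]
                l_mov, l_tgt = all_slot[l_sel], all_tgt[l_sel]
                r_mov, r_tgt = all_slot[r_sel], all_tgt[r_sel]

            if l_mov.size:
                old = L[l_mov]
                occ[l_tgt] = l_mov
                shared = R[l_mov] == old
                occ[old[~shared]] = -1
                L[l_mov] = l_tgt
                if has_ctcf:
                    hit = block_left[l_tgt]
                    if hit.any():
                        hs = l_mov[hit]
                        stall = rng.random(hs.size) < stall_p[spec[hs]]
                        l_stall[hs[stall]] = True
            if r_mov.size:
                old = R[r_mov]
                occ[r_tgt] = r_mov
                shared = L[r_mov] == old
                occ[old[~shared]] = -1
                R[r_mov] = r_tgt
                if has_ctcf:
                    hit = block_right[r_tgt]
                    if hit.any():
                        hs = r_mov[hit]
                        stall = rng.random(hs.size) < stall_p[spec[hs]]
                        r_stall[hs[stall]] = True

        # --- unloading ---------------------------------------------------
        idx = np.flatnonzero(alive[:n_ext])
        if idx.size:
            gone = idx[rng.random(idx.size) < koff_dt[spec[idx]]]
            if gone.size:
                loop_sizes.extend(((R[gone] - L[gone]) * site_kb).tolist())
                loop_spec.extend(spec[gone].tolist())
                occ[L[gone]] = -1
                occ[R[gone]] = -1
                alive[gone] = False

        # --- recording ---------------------------------------------------
        if step % record_steps == 0:
            idx = np.flatnonzero(alive[:n_ext])
            counts = np.bincount(spec[idx], minlength=n_species)
            rec_times.append(t)
            rec_density.append(counts / lattice_mb)
            if check_invariants:
                _validate_state(L, R, idx, occ, n_sites)

    # --- final state -----------------------------------------------------
    idx = np.flatnonzero(alive[:n_ext])
    adjacent = np.zeros(idx.size, dtype=bool)
    if idx.size:
        lm = L[idx] - 1
        rm = R[idx] + 1
        adjacent |= (lm >= 0) & (occ[np.clip(lm, 0, n_sites - 1)] >= 0)
        adjacent |= (rm < n_sites) & (occ[np.clip(rm, 0, n_sites - 1)] >= 0)
    is_paired = adjacent | (paired[idx] >= 0)
    paired_fraction = float(np.mean(is_paired)) if idx.size else 0.0

    states = [
        ExtruderState(
            id=int(k), species=species[spec[k]].name,
            left_anchor=float(L[k] * site_kb), right_anchor=float(R[k] * site_kb),
            left_stalled=bool(l_stall[k]), right_stalled=bool(r_stall[k]),
            paired_with=int(paired[k]) if paired[k] >= 0 else None,
            load_time=float(t_load[k]),
        )
        for k in idx
    ]
    depths, _ = nesting_stats(states) if states else (np.array([], dtype=int), 0.0)

    return SimResult(
        times=np.asarray(rec_times), density=np.asarray(rec_density),
        species_names=[s.name for s in species],
        loop_sizes=np.asarray(loop_sizes, dtype=float),
        loop_species=np.asarray(loop_spec, dtype=int),
        paired_fraction=paired_fraction, nesting_depths=depths,
        final_states=states, seed=seed,
    )


def _validate_state(L, R, idx, occ, n_sites):
    """Assert anchor ordering, lattice bounds, occupancy consistency and
    planarity (all loop intervals pairwise nested or disjoint)."""
    if idx.size == 0:
        return
    assert np.all(L[idx] <= R[idx]), "anchor crossing within an extruder"
    assert np.all((L[idx] >= 0) & (R[idx] < n_sites)), "anchor outside lattice"
    assert np.all(occ[L[idx]] == idx) and np.all(occ[R[idx]] == idx), \
        "occupancy table inconsistent"
    order = np.lexsort((-R[idx], L[idx]))
    stack: list[int] = []
    for k in order:
        l, r = L[idx[k]], R[idx[k]]
        while stack and stack[-1] < l:
            stack.pop()
        assert not (stack and stack[-1] < r), "crossing loop intervals"
        stack.append(r)


def _register_pairs(paired, pair_flag, spec, movers, blockers):
    """Mark mutually paired extruders for blocked arms of pairing species."""
    if movers.size == 0:
        return
    want = pair_flag[spec[movers]]
    m, b = movers[want], blockers[want]
    new = paired[m] == -1
    paired[m[new]] = b[new]
    newb = paired[b] == -1
    paired[b[newb]] = m[newb]


def nesting_stats(states: list, adjacency_kb: float = 1.0
                  ) -> tuple[np.ndarray, float]:
    """Nesting depth per loop and the paired fraction of a state list.

    Depth of a loop is the number of other loops strictly containing it.
    Raises on crossing (partially overlapping) loop intervals, which the
    simulator can never produce.  ``paired_fraction`` counts extruders with
    ``paired_with`` set or an anchor within ``adjacency_kb`` of another
    extruder's anchor.
    """
    if not states:
        return np.array([], dtype=int), 0.0
    order = sorted(range(len(states)),
                   key=lambda i: (states[i].left_anchor, -states[i].right_anchor))
    depths = np.zeros(len(states), dtype=int)
    stack: list[int] = []
    for i in order:
        s = states[i]
        while stack and states[stack[-1]].right_anchor < s.left_anchor:
            stack.pop()
        if stack and states[stack[-1]].right_anchor < s.right_anchor:
            raise ValueError(
                f"crossing loops: ({states[stack[-1]].left_anchor}, "
                f"{states[stack[-1]].right_anchor}) vs "
                f"({s.left_anchor}, {s.right_anchor})")
        depths[i] = len(stack)
        stack.append(i)

    anchors = []
    for i, s in enumerate(states):
        anchors.append((s.left_anchor, i))
        anchors.append((s.right_anchor, i))
    anchors.sort()
    adjacent = set()
    for (p1, i1), (p2, i2) in zip(anchors, anchors[1:]):
        if i1 != i2 and p2 - p1 <= adjacency_kb:
            adjacent.update((i1, i2))
    n_paired = sum(1 for i, s in enumerate(states)
                   if s.paired_with is not None or i in adjacent)
    return depths, n_paired / len(states)


def loops_to_distance_map(states: list, lattice_kb: float, bin_kb: float = 12.0,
                          step_nm_per_sqrt_kb: float = 25.0,
                          compaction: float = 0.25) -> DistanceMatrix:
    """Expected ideal-chain distance matrix implied by a loop configuration.

    The contour between two bins counts looped-out stretches at
    ``compaction`` per level of nesting (a kb covered by d loops
    contributes compaction**d kb of effective contour); expected distance
    is step_nm_per_sqrt_kb * sqrt(effective contour), the ideal-chain
    scaling.  Symmetric with a zero diagonal.
    """
    n_kb = int(round(lattice_kb))
    depth = np.zeros(n_kb + 1)
    for s in states:
        a, b = int(round(s.left_anchor)), int(round(s.right_anchor))
        depth[a] += 1
        depth[b] -= 1
    depth = np.cumsum(depth)[:n_kb]
    weight = compaction ** depth
    cum = np.concatenate([[0.0], np.cumsum(weight)])
    n_bins = int(np.ceil(n_kb / bin_kb))
    centers = np.clip(((np.arange(n_bins) + 0.5) * bin_kb).astype(int), 0, n_kb)
    w = cum[centers]
    contour = np.abs(w[:, None] - w[None, :])
    values = step_nm_per_sqrt_kb * np.sqrt(contour)
    return DistanceMatrix(values=values, counts=np.ones_like(values, dtype=int),
                          bin_kb=bin_kb)
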