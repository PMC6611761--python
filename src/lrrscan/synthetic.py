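"""Seeded generators for every input the pipeline consumes.

Each generator emits an analysis-ready object plus a
:class:`SyntheticTruth` ground-truth record (planted motif positions,
true substitutions, true doubling time, true band fractions, ...) so
every pipeline stage can be exercised and its recovery measured without
any external download.  The same parameters and seed always reproduce
identical output; there is no hidden global random state.

Default parameters mirror the experimental conditions the generators
emulate: growth curves start at 1e5 cells counted every 24 h for five
points (T0-T96); lanes carry three Gaussian bands (hexamer /
intermediate / monomer); images oppose a membrane ring (surface-marker
channel) to either a co-localized ring or an intracellular disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assays import ChannelPair, GrowthSeries, LaneProfile
from .conservation import AlignedSet
from .scanner import ResidueClassConfig
from .sequence import AMINO_ACIDS, ProteinSequence


class SyntheticError(ValueError):
    """Raised for inconsistent generator parameters."""


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside every generated artifact."""

    kind: str               # sequence | alignment | image | growth | lane
    parameters: dict
    truth: dict


#: Deterministic canonical consensus instantiations: every anchor is the
#: first member of its core class and every x position is G.
CANONICAL_WINDOWS = {11: "LGGLGLGGNGL", 12: "LGGLGLGGCGGL"}


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _freq_arrays(freqs: dict[str, float] | None):
    if freqs is None:
        freqs = {r: 1.0 / 20.0 for r in sorted(AMINO_ACIDS)}
    letters = sorted(freqs)
    probs = np.array([freqs[r] for r in letters], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
        raise SyntheticError("frequencies must be non-negative and sum to 1")
    return letters, probs / probs.sum(), freqs


def _plant_window(mode: str, variant: int, cfg: ResidueClassConfig,
                  letters, probs, rng) -> str:
    if mode == "canonical":
        return CANONICAL_WINDOWS[variant]
    if mode != "relaxed":
        raise SyntheticError(f"unknown plant mode {mode!r}")
    from .scanner import ANCHOR_POSITIONS

    window = [str(rng.choice(letters, p=probs)) for _ in range(variant)]
    anchors = ANCHOR_POSITIONS[variant]
    mid_class = cfg.n_class if variant == 11 else cfg.c_class
    # terminals drawn from core ∪ hydrophilic so hits survive any policy
    terminal_pool = sorted(cfg.l_core | cfg.hydrophilic_set)
    for pos in anchors:
        if pos == 9:
            pool = sorted(mid_class)
        elif pos in (1, variant):
            pool = terminal_pool
        else:
            pool = sorted(cfg.l_hydrophobic_ext)
        window[pos - 1] = str(rng.choice(pool))
    return "".join(window)


def gen_sequence(length: int, freqs: dict[str, float] | None = None,
                 plants=(), seed: int = 0,
                 cfg: ResidueClassConfig | None = None,
                 seq_id: str = "synthetic",
                 ) -> tuple[ProteinSequence, SyntheticTruth]:
    """Draw an i.i.d.-composition sequence with planted consensus windows.

    ``plants`` is a list of ``(position, mode)`` or
    ``(position, mode, variant)`` entries; mode ``"canonical"`` writes
    the deterministic core-class instantiation, ``"relaxed"`` samples
    anchors from the extended classes.  Plants must fit within the
    sequence without overlapping one another.
    """
    cfg = cfg or ResidueClassConfig()
    letters, probs, freqs = _freq_arrays(freqs)
    rng = _rng(seed)
    residues = list(rng.choice(letters, size=length, p=probs))

    normalized = []
    for plant in plants:
        position, mode, *rest = plant
        variant = rest[0] if rest else 11
        if variant not in (11, 12):
            raise SyntheticError(f"plant variant must be 11 or 12, got {variant}")
        if not (1 <= position and position + variant - 1 <= length):
            raise SyntheticError(
                f"plant at {position} (length {variant}) outside sequence "
                f"of length {length}")
        normalized.append((position, mode, variant))
    normalized.sort()
    for (p1, _, v1), (p2, _, _) in zip(normalized, normalized[1:]):
        if p1 + v1 - 1 >= p2:
            raise SyntheticError(f"plants at {p1} and {p2} overlap")

    from .scanner import ANCHOR_POSITIONS

    planted = []
    for position, mode, variant in normalized:
        window = _plant_window(mode, variant, cfg, letters, probs, rng)
        residues[position - 1 : position + variant - 1] = list(window)
        planted.append({
            "position": position, "mode": mode, "variant": variant,
            "window": window,
            "anchor_positions": [position + a - 1
                                 for a in ANCHOR_POSITIONS[variant]],
        })

    seq = ProteinSequence(id=seq_id, residues="".join(residues))
    truth = SyntheticTruth(
        kind="sequence",
        parameters={"length": length, "freqs": freqs, "seed": seed,
                    "plants": [tuple(p) for p in plants]},
        truth={"plants": planted},
    )
    return seq, truth


def planted_positions(truth: SyntheticTruth) -> list[int]:
    """Start positions of all planted windows."""
    return [p["position"] for p in truth.truth["plants"]]


def planted_anchor_positions(truth: SyntheticTruth) -> set[int]:
    """Full-sequence positions of every planted anchor (for protection)."""
    out: set[int] = set()
    for p in truth.truth["plants"]:
        out.update(p["anchor_positions"])
    return out


def gen_ortholog_set(base: ProteinSequence, n_rows: int = 3,
                     sub_rate: float = 0.05, mode: str = "conservative",
                     protected=(), seed: int = 0,
                     ) -> tuple[AlignedSet, SyntheticTruth]:
    """Derive an ungapped ortholog alignment by point substitution.

    Row 0 is the base sequence; each further row substitutes every
    position independently with probability ``sub_rate`` (new residue
    uniform over the other 19).  Mode ``"conservative"`` never touches
    the ``protected`` positions (typically planted anchor positions),
    so planted motifs stay conserved; ``"unconstrained"`` may hit them.
    No indels are generated — gap handling is exercised with scripted
    alignments.
    """
    if not 0.0 <= sub_rate <= 1.0:
        raise SyntheticError("sub_rate must be in [0, 1]")
    if mode not in ("conservative", "unconstrained"):
        raise SyntheticError(f"unknown ortholog mode {mode!r}")
    protected = set(protected) if mode == "conservative" else set()
    rng = _rng(seed)
    letters = sorted(AMINO_ACIDS)

    rows = [(base.id, base.residues)]
    substitutions: dict[str, list] = {}
    for k in range(1, n_rows):
        row_id = f"{base.id}_orth{k}"
        residues = list(base.residues)
        subs = []
        for idx in range(len(residues)):
            position = base.offset + idx
            if position in protected:
                continue
            if rng.random() < sub_rate:
                old = residues[idx]
                choices = [r for r in letters if r != old]
                new = str(rng.choice(choices))
                residues[idx] = new
                subs.append((position, old, new))
        rows.append((row_id, "".join(residues)))
        substitutions[row_id] = subs

    aln = AlignedSet(rows, offsets={rid: base.offset for rid, _ in rows})
    truth = SyntheticTruth(
        kind="alignment",
        parameters={"base_id": base.id, "n_rows": n_rows,
                    "sub_rate": sub_rate, "mode": mode,
                    "protected": sorted(protected), "seed": seed},
        truth={"substitutions": substitutions},
    )
    return aln, truth


def gen_channel_pair(mode: str = "membrane/membrane", image_size: int = 128,
                     ring_radius: float = 40.0, ring_width: float = 8.0,
                     intensity: float = 100.0, noise_sigma: float = 0.0,
                     seed: int = 0) -> tuple[ChannelPair, SyntheticTruth]:
    """Two-channel image: surface-marker ring vs ring or intracellular disc.

    Channel A is always a membrane ring with a Gaussian radial
    cross-section (peak ``intensity`` at ``ring_radius``, width set by
    ``ring_width``), as a point-spread-blurred membrane appears in a
    confocal section.  In ``"membrane/membrane"`` mode channel B is the
    identical ring (a surface-localized construct); in
    ``"membrane/intracellular"`` it is a Gaussian disc strictly
    interior to the ring (a construct retained inside the cell), whose
    above-threshold mask is disjoint from the ring's.  Gaussian noise
    is added and clipped at zero; thresholds default to half the peak
    intensity.
    """
    if mode not in ("membrane/membrane", "membrane/intracellular"):
        raise SyntheticError(f"unknown image mode {mode!r}")
    if ring_radius + ring_width / 2 >= image_size / 2:
        raise SyntheticError("ring does not fit in the image")
    rng = _rng(seed)
    center = (image_size - 1) / 2.0
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    r = np.hypot(yy - center, xx - center)

    ring_sigma = ring_width / 2.0
    channel_a = intensity * np.exp(-((r - ring_radius) ** 2)
                                   / (2 * ring_sigma ** 2))
    if mode == "membrane/membrane":
        channel_b = channel_a.copy()
    else:
        disc_sigma = max(1.0, (ring_radius - 1.5 * ring_width) / 2.0)
        channel_b = intensity * np.exp(-(r ** 2) / (2 * disc_sigma ** 2))
    threshold = intensity / 2.0
    mask_a = channel_a > threshold
    mask_b = channel_b > threshold
    if noise_sigma > 0:
        channel_a = np.clip(channel_a + rng.normal(0, noise_sigma,
                                                   channel_a.shape), 0, None)
        channel_b = np.clip(channel_b + rng.normal(0, noise_sigma,
                                                   channel_b.shape), 0, None)

    pair = ChannelPair(channel_a=channel_a, channel_b=channel_b,
                       threshold_a=threshold, threshold_b=threshold)
    truth = SyntheticTruth(
        kind="image",
        parameters={"mode": mode, "image_size": image_size,
                    "ring_radius": ring_radius, "ring_width": ring_width,
                    "intensity": intensity, "noise_sigma": noise_sigma,
                    "seed": seed},
        truth={"ring_pixels": int(mask_a.sum()), "b_pixels": int(mask_b.sum()),
               "masks_disjoint": not bool((mask_a & mask_b).any())
               if mode == "membrane/intracellular" else False},
    )
    return pair, truth


def gen_growth(n0: float = 1e5, dt_hours: float = 24.0,
               times=(0.0, 24.0, 48.0, 72.0, 96.0),
               noise_sigma: float = 0.05, dead_rate: float = 0.03,
               seed: int = 0) -> tuple[GrowthSeries, SyntheticTruth]:
    """Exponential growth with multiplicative log-normal noise.

    Total cells at time t are ``n0 * 2**(t/dt) * exp(eps)`` with
    ``eps ~ Normal(0, noise_sigma)`` (noise 0 gives exact doublings);
    dead cells are a binomial draw of the total at ``dead_rate`` and
    live = total - dead, so the expected dead fraction equals
    ``dead_rate`` and the live curve keeps the true doubling time.
    """
    if dt_hours <= 0:
        raise SyntheticError("dt_hours must be positive")
    if not 0.0 <= dead_rate < 1.0:
        raise SyntheticError("dead_rate must be in [0, 1)")
    rng = _rng(seed)
    times = np.asarray(times, dtype=float)
    eps = rng.normal(0.0, noise_sigma, size=times.shape) if noise_sigma > 0 \
        else np.zeros_like(times)
    total = np.rint(n0 * np.power(2.0, times / dt_hours) * np.exp(eps))
    total = total.astype(int)
    dead = rng.binomial(total, dead_rate) if dead_rate > 0 \
        else np.zeros_like(total)
    series = GrowthSeries(times=times, live_counts=(total - dead).astype(float),
                          dead_counts=dead.astype(float))
    truth = SyntheticTruth(
        kind="growth",
        parameters={"n0": n0, "dt_hours": dt_hours, "times": list(times),
                    "noise_sigma": noise_sigma, "dead_rate": dead_rate,
                    "seed": seed},
        truth={"dt_hours": dt_hours, "dead_rate": dead_rate},
    )
    return series, truth


def gen_lane(band_positions=(30.0, 55.0, 80.0),
             band_fractions=(0.5, 0.3, 0.2), peak_width: float = 3.0,
             noise_sigma: float = 0.01, seed: int = 0, labels=None,
             step: float = 0.25) -> tuple[LaneProfile, SyntheticTruth]:
    """Lane profile of Gaussian bands with declared quantification windows.

    Band fractions must sum to 1 (within 1e-6); intensity is the sum of
    fraction-weighted Gaussians plus Gaussian noise scaled by
    ``noise_sigma`` * (tallest peak), clipped at zero.  Band windows
    are set at +/- 3 peak widths around each band position.
    """
    positions = np.asarray(band_positions, dtype=float)
    fractions = np.asarray(band_fractions, dtype=float)
    if positions.shape != fractions.shape:
        raise SyntheticError("band positions and fractions must pair up")
    if len(np.unique(positions)) != len(positions):
        raise SyntheticError("band positions must be distinct")
    if abs(fractions.sum() - 1.0) > 1e-6:
        raise SyntheticError(f"band fractions sum to {fractions.sum()}, not 1")
    if peak_width <= 0:
        raise SyntheticError("peak_width must be positive")
    labels = list(labels) if labels is not None else \
        [f"band{i + 1}" for i in range(len(positions))]

    rng = _rng(seed)
    lo = max(0.0, positions.min() - 6 * peak_width)
    hi = positions.max() + 6 * peak_width
    x = np.arange(lo, hi + step, step)
    signal = np.zeros_like(x)
    for p, f in zip(positions, fractions):
        signal += f * np.exp(-((x - p) ** 2) / (2 * peak_width ** 2))
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma * signal.max(),
                                     size=signal.shape)
    signal = np.clip(signal, 0.0, None)

    windows = [(label, float(p - 3 * peak_width), float(p + 3 * peak_width))
               for label, p in zip(labels, positions)]
    profile = LaneProfile(positions=x, intensity=signal, band_windows=windows)
    truth = SyntheticTruth(
        kind="lane",
        parameters={"band_positions": list(map(float, positions)),
                    "band_fractions": list(map(float, fractions)),
                    "peak_width": peak_width, "noise_sigma": noise_sigma,
                    "seed": seed, "step": step},
        truth={"fractions": dict(zip(labels, map(float, fractions)))},
    )
    return profile, truth
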