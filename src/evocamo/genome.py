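"""Genetic-programming genomes that render to greyscale target patterns.

A genome is a finite expression tree.  Leaves produce base fields (constant
luminance, coordinate gradients, texture lookups, seeded value noise) and
internal nodes combine or warp their children (arithmetic, min/max,
thresholding, sine gratings, coordinate rotation/scaling, blending).
Evaluating the root over the target's pixel grid and clamping to [0, 255]
yields the 75 x 100 px greyscale pattern shown on a moving target.

Everything is deterministic: the same genome and texture library always
render to the bit-identical image, and generation/mutation consume explicit
NumPy Generators.  Arithmetic stays in floating point throughout; values are
clamped and quantized to 8-bit only at the final render step, so intermediate
nodes may freely leave [0, 255].

Coordinate convention: origin at the top-left, x rightward, y downward,
pixel centers at half-integers.  "Vertical stripes" therefore vary along x.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

TARGET_WIDTH = 75
TARGET_HEIGHT = 100

__all__ = [
    "GeneNode",
    "PatternGenome",
    "OPERATORS",
    "random_genome",
    "render_genome",
    "mutate_genome",
    "serialize_genome",
    "parse_genome",
    "default_texture_library",
]


# ---------------------------------------------------------------------------
# Operator table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Operator:
    name: str
    arity: int
    # (low, high) per parameter; used for random draws and jitter scale
    param_ranges: tuple[tuple[float, float], ...]
    fn: Callable

    @property
    def n_params(self) -> int:
        return len(self.param_ranges)


def _value_noise(x, y, seed_p, cell):
    """Seeded lattice value noise, bilinearly interpolated.

    The lattice values are a pure function of (seed_p, lattice index) so the
    field is deterministic and translation-consistent.
    """
    cell = max(float(cell), 1.0)
    gx = x / cell
    gy = y / cell
    ix = np.floor(gx).astype(np.int64)
    iy = np.floor(gy).astype(np.int64)
    fx = gx - ix
    fy = gy - iy

    def lattice(i, j):
        # integer hash -> [0, 255]; vectorized, stable across platforms
        h = (i * np.int64(73856093)) ^ (j * np.int64(19349663)) ^ np.int64(int(seed_p) * 83492791)
        h = (h ^ (h >> 13)) * np.int64(1274126177)
        h = h ^ (h >> 16)
        return (h & np.int64(0xFFFF)).astype(np.float64) / 65535.0 * 255.0

    sx = fx * fx * (3 - 2 * fx)  # smoothstep
    sy = fy * fy * (3 - 2 * fy)
    v00 = lattice(ix, iy)
    v10 = lattice(ix + 1, iy)
    v01 = lattice(ix, iy + 1)
    v11 = lattice(ix + 1, iy + 1)
    return (v00 * (1 - sx) + v10 * sx) * (1 - sy) + (v01 * (1 - sx) + v11 * sx) * sy


def _texture_lookup(ctx, x, y, idx, off_x, off_y, scale):
    textures = ctx["textures"]
    tex = textures[int(abs(idx)) % len(textures)]
    h, w = tex.shape
    xi = np.floor(x * scale + off_x).astype(np.int64) % w
    yi = np.floor(y * scale + off_y).astype(np.int64) % h
    return tex[yi, xi].astype(np.float64)


def _rot_coords(x, y, angle_deg):
    cx, cy = TARGET_WIDTH / 2.0, TARGET_HEIGHT / 2.0
    a = np.deg2rad(angle_deg)
    dx, dy = x - cx, y - cy
    return (cx + dx * np.cos(a) - dy * np.sin(a), cy + dx * np.sin(a) + dy * np.cos(a))


def _scale_coords(x, y, sx, sy):
    cx, cy = TARGET_WIDTH / 2.0, TARGET_HEIGHT / 2.0
    sx = sx if abs(sx) > 1e-6 else 1e-6
    sy = sy if abs(sy) > 1e-6 else 1e-6
    return (cx + (x - cx) / sx, cy + (y - cy) / sy)


def _sine_warp(child_val, x, y, orient_deg, period, phase, amplitude):
    """Sine grating whose phase is spatially warped by the child field.

    With a mid-grey (127) child this is a pure grating of the given
    orientation, period, phase, and amplitude; orientation 0 gives vertical
    stripes (intensity varies along x).
    """
    period = max(abs(period), 1.0)
    a = np.deg2rad(orient_deg)
    s = x * np.cos(a) + y * np.sin(a)
    warp = (child_val - 127.0) / 255.0 * np.pi
    return 127.0 + amplitude * np.sin(2 * np.pi * s / period + phase + warp)


# Each fn takes (ctx, x, y, params, child_evaluator) where child_evaluator(i, x, y)
# lazily evaluates child i on (possibly transformed) coordinates.
OPERATORS: dict[str, Operator] = {}


def _register(name, arity, param_ranges, fn):
    OPERATORS[name] = Operator(name, arity, tuple(tuple(p) for p in param_ranges), fn)


# -- terminals --
_register("const", 0, [(0.0, 255.0)], lambda ctx, x, y, p, ev: np.full_like(x, p[0]))
_register("coord_x", 0, [], lambda ctx, x, y, p, ev: x / TARGET_WIDTH * 255.0)
_register("coord_y", 0, [], lambda ctx, x, y, p, ev: y / TARGET_HEIGHT * 255.0)
_register(
    "texture", 0, [(0.0, 64.0), (0.0, 128.0), (0.0, 128.0), (0.25, 4.0)],
    lambda ctx, x, y, p, ev: _texture_lookup(ctx, x, y, *p),
)
_register(
    "noise", 0, [(0.0, 1e6), (4.0, 64.0)],
    lambda ctx, x, y, p, ev: _value_noise(x, y, p[0], p[1]),
)

# -- arity 1 --
_register("absolute", 1, [], lambda ctx, x, y, p, ev: 2.0 * np.abs(ev(0, x, y) - 127.0))
_register(
    "threshold", 1, [(0.0, 255.0)],
    lambda ctx, x, y, p, ev: np.where(ev(0, x, y) >= p[0], 255.0, 0.0),
)
_register(
    "sine_warp", 1, [(0.0, 180.0), (2.0, 64.0), (0.0, 2 * np.pi), (0.0, 127.0)],
    lambda ctx, x, y, p, ev: _sine_warp(ev(0, x, y), x, y, *p),
)
_register(
    "rotate", 1, [(0.0, 360.0)],
    lambda ctx, x, y, p, ev: ev(0, *_rot_coords(x, y, p[0])),
)
_register(
    "scale", 1, [(0.25, 4.0), (0.25, 4.0)],
    lambda ctx, x, y, p, ev: ev(0, *_scale_coords(x, y, p[0], p[1])),
)

# -- arity 2 --
_register("add", 2, [], lambda ctx, x, y, p, ev: ev(0, x, y) + ev(1, x, y))
_register("subtract", 2, [], lambda ctx, x, y, p, ev: ev(0, x, y) - ev(1, x, y))
_register(
    "multiply", 2, [],
    lambda ctx, x, y, p, ev: ev(0, x, y) * ev(1, x, y) / 255.0,
)
_register("minimum", 2, [], lambda ctx, x, y, p, ev: np.minimum(ev(0, x, y), ev(1, x, y)))
_register("maximum", 2, [], lambda ctx, x, y, p, ev: np.maximum(ev(0, x, y), ev(1, x, y)))

# -- arity 3 --
def _blend(ctx, x, y, p, ev):
    w = np.clip(ev(2, x, y) / 255.0, 0.0, 1.0)
    return ev(0, x, y) * (1.0 - w) + ev(1, x, y) * w


_register("blend", 3, [], _blend)

TERMINALS = [op for op in OPERATORS.values() if op.arity == 0]
INTERNALS = [op for op in OPERATORS.values() if op.arity > 0]


# ---------------------------------------------------------------------------
# Genome types
# ---------------------------------------------------------------------------

@dataclass
class GeneNode:
    """One node of a pattern program: operator name, real parameters, children."""

    op_name: str
    params: list[float] = field(default_factory=list)
    children: list["GeneNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        op = OPERATORS.get(self.op_name)
        if op is None:
            raise ValueError(f"unknown operator {self.op_name!r}")
        if len(self.children) != op.arity:
            raise ValueError(
                f"operator {self.op_name!r} expects {op.arity} children, "
                f"got {len(self.children)}"
            )
        if len(self.params) != op.n_params:
            raise ValueError(
                f"operator {self.op_name!r} expects {op.n_params} params, "
                f"got {len(self.params)}"
            )
        if not all(np.isfinite(self.params)):
            raise ValueError(f"non-finite parameter in {self.op_name!r} node")

    def depth(self) -> int:
        return 1 + (max((c.depth() for c in self.children), default=0))

    def n_nodes(self) -> int:
        return 1 + sum(c.n_nodes() for c in self.children)

    def copy(self) -> "GeneNode":
        return GeneNode(self.op_name, list(self.params), [c.copy() for c in self.children])

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PatternGenome:
    """A pattern program plus bookkeeping identity and lineage."""

    root: GeneNode
    genome_id: str
    lineage: str | None = None

    @property
    def depth(self) -> int:
        return self.root.depth()

    def copy(self) -> "PatternGenome":
        return PatternGenome(self.root.copy(), self.genome_id, self.lineage)


def _structure_digest(root: GeneNode) -> str:
    return hashlib.sha1(serialize_tree(root).encode()).hexdigest()[:10]


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------

def _random_params(op: Operator, rng: np.random.Generator) -> list[float]:
    return [float(rng.uniform(lo, hi)) for lo, hi in op.param_ranges]


def _random_tree(rng: np.random.Generator, depth: int, max_depth: int,
                 p_terminal: float = 0.35) -> GeneNode:
    if depth >= max_depth or (depth > 1 and rng.random() < p_terminal):
        op = TERMINALS[rng.integers(len(TERMINALS))]
    else:
        op = INTERNALS[rng.integers(len(INTERNALS))]
    children = [_random_tree(rng, depth + 1, max_depth) for _ in range(op.arity)]
    return GeneNode(op.name, _random_params(op, rng), children)


def random_genome(seed: int, max_depth: int = 8) -> PatternGenome:
    """Draw a random pattern program of depth <= ``max_depth``.

    The same seed always yields the same genome.  ``max_depth == 1`` forces a
    single terminal node.
    """
    if max_depth < 1:
        raise ValueError(f"max_depth must be >= 1, got {max_depth}")
    rng = np.random.default_rng(seed)
    root = _random_tree(rng, 1, max_depth)
    return PatternGenome(root, genome_id=f"s{seed}-{_structure_digest(root)}")


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def default_texture_library(seed: int = 2021, n: int = 4, size: int = 128) -> list[np.ndarray]:
    """Small library of greyscale source textures for the texture terminal.

    Synthetic stand-ins for natural source photographs: band-limited value
    noise at a few scales, quantized to 8-bit.
    """
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:size, 0:size].astype(np.float64) + 0.5
    lib = []
    for i in range(n):
        cell = float(rng.uniform(6, 32))
        img = _value_noise(x, y, float(rng.integers(1, 1e6)), cell)
        lib.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return lib


_DEFAULT_TEXTURES: list[np.ndarray] | None = None


def _textures_or_default(texture_library) -> Sequence[np.ndarray]:
    global _DEFAULT_TEXTURES
    if texture_library:
        return list(texture_library)
    if _DEFAULT_TEXTURES is None:
        _DEFAULT_TEXTURES = default_texture_library()
    return _DEFAULT_TEXTURES


def _eval_node(node: GeneNode, ctx: dict, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    op = OPERATORS[node.op_name]

    def ev(i, xx, yy):
        return _eval_node(node.children[i], ctx, xx, yy)

    out = op.fn(ctx, x, y, node.params, ev)
    return np.nan_to_num(out, nan=127.0, posinf=255.0, neginf=0.0)


def render_genome(
    genome: PatternGenome,
    texture_library: Sequence[np.ndarray] | None = None,
    width: int = TARGET_WIDTH,
    height: int = TARGET_HEIGHT,
) -> np.ndarray:
    """Render a genome to a ``(height, width)`` uint8 greyscale image.

    Pure: identical genome + library give bit-identical pixels.  Evaluation
    runs in float64; non-finite values are mapped to greys and the result is
    clamped to [0, 255] before 8-bit quantization.
    """
    textures = _textures_or_default(texture_library)
    y, x = np.mgrid[0:height, 0:width].astype(np.float64) + 0.5
    vals = _eval_node(genome.root, {"textures": textures}, x, y)
    return np.clip(np.rint(vals), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

DEFAULT_MUTATION_MODES = ("jitter", "swap", "subtree")


def _jitter_params(node: GeneNode, op: Operator, rng) -> None:
    for i, (lo, hi) in enumerate(op.param_ranges):
        sd = 0.10 * (hi - lo)
        node.params[i] = float(np.clip(node.params[i] + rng.normal(0.0, sd), lo, hi))


def _swap_operator(node: GeneNode, op: Operator, rng) -> None:
    peers = [o for o in OPERATORS.values() if o.arity == op.arity and o.name != op.name]
    if not peers:
        return
    new_op = peers[rng.integers(len(peers))]
    node.op_name = new_op.name
    node.params = _random_params(new_op, rng)


def _truncate_to_depth(node: GeneNode, depth: int, max_depth: int, rng) -> GeneNode:
    if depth >= max_depth and node.children:
        op = TERMINALS[rng.integers(len(TERMINALS))]
        return GeneNode(op.name, _random_params(op, rng), [])
    node.children = [
        _truncate_to_depth(c, depth + 1, max_depth, rng) for c in node.children
    ]
    return node


def mutate_genome(
    genome: PatternGenome,
    rng: np.random.Generator,
    mutation_rate: float = 0.05,
    max_depth: int = 8,
    modes: tuple[str, ...] = DEFAULT_MUTATION_MODES,
) -> PatternGenome:
    """Return a mutated copy with a fresh id and lineage set to the parent.

    Each node independently mutates with probability ``mutation_rate``; a
    mutating node undergoes one of the enabled modes (chosen uniformly):
    ``jitter`` (Gaussian parameter perturbation, sd 10% of the parameter
    range), ``swap`` (operator swap of equal arity, parameters redrawn), or
    ``subtree`` (replacement by a random subtree of depth <= 3).  The tree is
    truncated back to ``max_depth`` afterwards.  Rate 0 copies the tree
    structurally unchanged.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError(f"mutation_rate must lie in [0, 1], got {mutation_rate}")
    if not modes:
        raise ValueError("at least one mutation mode required")
    root = genome.root.copy()
    if mutation_rate > 0:
        for node in list(root.walk()):
            if rng.random() >= mutation_rate:
                continue
            mode = modes[rng.integers(len(modes))]
            op = OPERATORS[node.op_name]
            if mode == "jitter":
                _jitter_params(node, op, rng)
            elif mode == "swap":
                _swap_operator(node, op, rng)
            elif mode == "subtree":
                sub = _random_tree(rng, 1, 3)
                node.op_name = sub.op_name
                node.params = sub.params
                node.children = sub.children
            else:
                raise ValueError(f"unknown mutation mode {mode!r}")
        root = _truncate_to_depth(root, 1, max_depth, rng)
    nonce = rng.integers(0, 2**63 - 1)
    new_id = f"m{nonce:016x}-{_structure_digest(root)}"
    return PatternGenome(root, genome_id=new_id, lineage=genome.genome_id)


# ---------------------------------------------------------------------------
# Serialization: nested S-expressions
# ---------------------------------------------------------------------------

def serialize_tree(node: GeneNode) -> str:
    parts = [node.op_name]
    parts += [repr(float(p)) for p in node.params]
    parts += [serialize_tree(c) for c in node.children]
    return "(" + " ".join(parts) + ")"


def serialize_genome(genome: PatternGenome) -> str:
    """One-line S-expression; ``repr`` floats make the round trip exact."""
    return serialize_tree(genome.root)


class GenomeParseError(ValueError):
    pass


def _tokenize(text: str) -> list[str]:
    return text.replace("(", " ( ").replace(")", " ) ").split()


def _parse_tokens(tokens: list[str], pos: int) -> tuple[GeneNode, int]:
    if pos >= len(tokens) or tokens[pos] != "(":
        got = tokens[pos] if pos < len(tokens) else "end of input"
        raise GenomeParseError(f"expected '(' at token {pos}, got {got!r}")
    pos += 1
    if pos >= len(tokens):
        raise GenomeParseError("unexpected end of input after '('")
    op_name = tokens[pos]
    op = OPERATORS.get(op_name)
    if op is None:
        raise GenomeParseError(f"unknown operator {op_name!r} at token {pos}")
    pos += 1
    params: list[float] = []
    children: list[GeneNode] = []
    while pos < len(tokens) and tokens[pos] != ")":
        if tokens[pos] == "(":
            child, pos = _parse_tokens(tokens, pos)
            children.append(child)
        else:
            try:
                params.append(float(tokens[pos]))
            except ValueError as exc:
                raise GenomeParseError(f"bad token {tokens[pos]!r} at {pos}") from exc
            pos += 1
    if pos >= len(tokens):
        raise GenomeParseError(f"missing ')' for {op_name!r}")
    try:
        node = GeneNode(op_name, params, children)
    except ValueError as exc:
        raise GenomeParseError(str(exc)) from exc
    return node, pos + 1


def parse_genome(text: str, genome_id: str | None = None) -> PatternGenome:
    """Parse an S-expression back into a genome.

    Malformed input raises :class:`GenomeParseError` naming the offending
    token.  The genome id defaults to a digest of the parsed structure.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GenomeParseError("empty genome text")
    root, pos = _parse_tokens(tokens, 0)
    if pos != len(tokens):
        raise GenomeParseError(f"trailing tokens after genome: {tokens[pos]!r}")
    return PatternGenome(root, genome_id=genome_id or f"p-{_structure_digest(root)}")
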