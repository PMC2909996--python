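"""Nearest-neighbor duplex melting temperatures for primer/target pairs.

The melting temperature of a primer–template duplex is computed from the
two-state nearest-neighbor model:

    Tm(K) = ΔH° / (ΔS° + R·ln(cT/4))        (non-self-complementary duplex)

with ΔH°, ΔS° summed over dinucleotide stacks (SantaLucia 1998 unified
Watson–Crick set, plus the published single-internal-mismatch and
terminal-mismatch sets), R = 1.987 cal/(mol·K) and cT the total strand
concentration. Monovalent-salt correction defaults to Owczarzy et al.
(2004); the Schildkraut–Lifson 16.6·log10[Na+] and the SantaLucia
entropic 0.368·N·ln[Na+] forms are available as options.

The two environmental constants (monovalent salt, strand concentration)
are not hard-coded: :func:`calibrate_model` fits them to user-supplied
anchor Tm values, and the package ships constants calibrated against two
reference ITS primers (see ``data/tm_calibration.yaml``).
"""

from __future__ import annotations

import importlib.resources as resources
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import least_squares

from ._iupac import IUPAC_SETS, reverse_complement, validate_iupac

R_GAS = 1.987  # cal/(mol·K)
_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


class CalibrationError(RuntimeError):
    """Raised when the environmental constants cannot reproduce the anchors."""


@dataclass(frozen=True)
class NNParameterSet:
    """ΔH°/ΔS° lookup tables keyed by stack strings ``XY/WZ``.

    ``XY`` is the top strand 5'→3', ``WZ`` the bottom strand 3'→5'.
    A stack and its 180°-rotated equivalent (``ZW/YX``) share parameters.
    """

    wc: dict[str, tuple[float, float]]
    init: dict[str, tuple[float, float]]
    imm: dict[str, tuple[float, float]]
    tmm: dict[str, tuple[float, float]]
    version: str = "1"

    def __post_init__(self) -> None:
        for top in itertools.product("ACGT", repeat=2):
            key = f"{top[0]}{top[1]}/{_WC[top[0]]}{_WC[top[1]]}"
            if self._rotlookup(self.wc, key) is None:
                raise ValueError(f"Watson-Crick stack missing from table: {key}")

    @staticmethod
    def _rotlookup(table: dict[str, tuple[float, float]], key: str):
        if key in table:
            return table[key]
        top, bot = key.split("/")
        rot = f"{bot[::-1]}/{top[::-1]}"
        return table.get(rot)

    def stack(self, top2: str, bot2: str) -> tuple[float, float]:
        """Parameters for one dinucleotide stack; mismatch stacks missing
        from the published sets (e.g. tandem mismatches) contribute zero."""
        key = f"{top2}/{bot2}"
        for table in (self.wc, self.imm, self.tmm):
            hit = self._rotlookup(table, key)
            if hit is not None:
                return hit
        return (0.0, 0.0)

    def initiation(self, base: str) -> tuple[float, float]:
        return self.init["init_G/C"] if base in "GC" else self.init["init_A/T"]


def load_nn_params() -> NNParameterSet:
    """Load the versioned nearest-neighbor parameter asset."""
    tables: dict[str, dict[str, tuple[float, float]]] = {
        "wc": {}, "init": {}, "imm": {}, "tmm": {}}
    path = resources.files("itspcr.data") / "nn_params.tsv"
    with path.open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, stack, dh, ds = line.rstrip("\n").split("\t")
            tables[kind][stack] = (float(dh), float(ds))
    return NNParameterSet(**tables)


@dataclass(frozen=True)
class TmModel:
    """Nearest-neighbor parameters plus environmental constants."""

    params: NNParameterSet
    monovalent_salt: float = 0.05      # mol/L Na+ equivalents
    strand_concentration: float = 2.5e-7  # mol/L total strand (cT)
    salt_correction: str = "owczarzy"  # owczarzy | schildkraut | santalucia
    gas_constant: float = R_GAS
    calibration_residuals: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.strand_concentration <= 0:
            raise ValueError("salt and strand concentration must be positive")
        if self.salt_correction not in ("owczarzy", "schildkraut", "santalucia"):
            raise ValueError(f"unknown salt correction {self.salt_correction!r}")


def _resolve_degenerate(primer: str, bottom: str) -> str:
    """Resolve degenerate primer positions to concrete bases.

    A degenerate primer is a pool of concrete oligos; the best-matching
    member dominates the duplex population. Each degenerate position is
    resolved to the complement of the paired target base when that base
    is in the position's set (fewest mismatches); remaining positions are
    enumerated and the most stable (highest-Tm proxy: here, resolved
    lazily by the caller via full enumeration) — at this level we return
    the candidate lists for enumeration.
    """
    fixed: list[str | tuple[str, ...]] = []
    for p, b in zip(primer, bottom):
        cands = IUPAC_SETS[p]
        if len(cands) == 1:
            fixed.append(next(iter(cands)))
        elif b in "ACGT" and _WC[b] in cands:
            fixed.append(_WC[b])
        else:
            fixed.append(tuple(sorted(cands)))
    return fixed


def _duplex_dh_ds(top: str, bottom: str, params: NNParameterSet) -> tuple[float, float]:
    """Sum stack and initiation terms for a concrete duplex.

    ``top`` is the primer 5'→3'; ``bottom`` is the target aligned under it
    3'→5' (i.e. bottom[i] pairs top[i]).
    """
    n = len(top)
    dh, ds = 0.0, 0.0
    matched = [_WC.get(t) == b for t, b in zip(top, bottom)]
    for i in range(n - 1):
        top2, bot2 = top[i:i + 2], bottom[i:i + 2]
        if matched[i] and matched[i + 1]:
            h, s = params._rotlookup(params.wc, f"{top2}/{bot2}")
        elif matched[i] ^ matched[i + 1]:
            terminal = (i == 0 and not matched[0]) or (i == n - 2 and not matched[n - 1])
            key = f"{top2}/{bot2}"
            hit = None
            if terminal:
                hit = params._rotlookup(params.tmm, key)
            if hit is None:
                hit = params._rotlookup(params.imm, key)
            h, s = hit if hit is not None else (0.0, 0.0)
        else:  # tandem mismatch: no published single-mismatch stack applies
            h, s = (0.0, 0.0)
        dh += h
        ds += s
    for end in (top[0], top[-1]):
        h, s = params.initiation(end)
        dh += h
        ds += s
    return dh, ds


def _tm_from_dh_ds(dh: float, ds: float, model: TmModel, seq: str) -> float:
    """Apply the concentration term and salt correction; return °C."""
    na, ct = model.monovalent_salt, model.strand_concentration
    n_phosphates = len(seq) - 1
    if model.salt_correction == "santalucia":
        ds = ds + 0.368 * n_phosphates * math.log(na)
    t_kelvin = dh * 1000.0 / (ds + model.gas_constant * math.log(ct / 4.0))
    if model.salt_correction == "schildkraut":
        return t_kelvin - 273.15 + 16.6 * math.log10(na)
    if model.salt_correction == "owczarzy":
        fgc = (seq.count("G") + seq.count("C")) / len(seq)
        inv = (1.0 / t_kelvin
               + (4.29 * fgc - 3.95) * 1e-5 * math.log(na)
               + 9.40e-6 * math.log(na) ** 2)
        return 1.0 / inv - 273.15
    return t_kelvin - 273.15


def duplex_tm(primer: str, target_window: str, model: TmModel) -> float:
    """Tm (°C) of a primer annealed to an equal-length target window.

    The window is given 5'→3' as the strand the primer anneals to, so a
    perfect target is the primer's reverse complement. Degenerate primer
    positions are resolved to the best-matching concrete base (ties
    broken toward higher Tm) before thermodynamic lookup.
    """
    primer = primer.upper()
    target_window = target_window.upper()
    if len(primer) != len(target_window):
        raise ValueError("primer and target window must have equal length")
    if "-" in target_window or not validate_iupac(target_window) or not validate_iupac(primer):
        raise ValueError("sequences must be gap-free IUPAC strings")
    bottom = target_window[::-1]  # bottom[i] pairs primer[i]
    slots = _resolve_degenerate(primer, bottom)
    open_positions = [i for i, s in enumerate(slots) if isinstance(s, tuple)]
    if not open_positions:
        top = "".join(slots)  # type: ignore[arg-type]
        dh, ds = _duplex_dh_ds(top, bottom, model.params)
        return _tm_from_dh_ds(dh, ds, model, top)
    # enumerate remaining degenerate choices; keep the most stable duplex
    best = -math.inf
    choices = [slots[i] for i in open_positions]
    if math.prod(len(c) for c in choices) > 4096:
        raise ValueError("primer too degenerate to resolve exhaustively")
    for combo in itertools.product(*choices):
        concrete = list(slots)
        for pos, base in zip(open_positions, combo):
            concrete[pos] = base
        top = "".join(concrete)  # type: ignore[arg-type]
        dh, ds = _duplex_dh_ds(top, bottom, model.params)
        best = max(best, _tm_from_dh_ds(dh, ds, model, top))
    return best


def tm_perfect(primer: str, model: TmModel) -> float:
    """Tm of the primer against its perfect complement."""
    primer = primer.upper()
    if len(primer) < 8:
        raise ValueError("primer shorter than 8 nt")
    return duplex_tm(primer, reverse_complement(primer), model)


#: physically plausible PCR conditions; calibration stays inside these
CALIBRATION_BOUNDS = ((1e-3, 1.0), (1e-12, 1e-4))


def calibrate_model(anchors: list[tuple[str, float]],
                    params: NNParameterSet | None = None,
                    salt_correction: str = "owczarzy",
                    max_anchor_residual: float = 1.0) -> TmModel:
    """Fit salt and strand concentration to anchor (primer, Tm °C) pairs.

    Least-squares in log-parameter space, multi-started, constrained to
    physically plausible PCR conditions (salt 1 mM–1 M, total strand
    1 pM–100 µM). Residuals per anchor are stored on the returned model;
    failure to bring every anchor within ``max_anchor_residual`` °C
    raises :class:`CalibrationError` rather than silently returning a
    poor model.
    """
    if len(anchors) < 2 or len({a[0].upper() for a in anchors}) < 2:
        raise ValueError("need at least two anchors with distinct primers")
    params = params or load_nn_params()

    def residuals(logp: np.ndarray) -> np.ndarray:
        model = TmModel(params, math.exp(logp[0]), math.exp(logp[1]),
                        salt_correction=salt_correction)
        return np.array([tm_perfect(seq, model) - tm for seq, tm in anchors])

    (na_lo, na_hi), (ct_lo, ct_hi) = CALIBRATION_BOUNDS
    lb = np.log([na_lo, ct_lo])
    ub = np.log([na_hi, ct_hi])
    best = None
    for na0 in (5e-3, 5e-2, 0.5):
        for ct0 in (1e-10, 1e-7, 1e-5):
            sol = least_squares(residuals, np.log([na0, ct0]), bounds=(lb, ub))
            if best is None or sol.cost < best.cost:
                best = sol
    assert best is not None
    na, ct = math.exp(best.x[0]), math.exp(best.x[1])
    resid = {seq: float(r) for (seq, _), r in zip(anchors, best.fun)}
    model = TmModel(params, na, ct, salt_correction=salt_correction,
                    calibration_residuals=resid)
    worst = max(abs(r) for r in resid.values())
    if worst >= max_anchor_residual:
        raise CalibrationError(
            f"calibration residual {worst:.2f} °C exceeds "
            f"{max_anchor_residual} °C on anchors: {resid}")
    return model


def default_model(params: NNParameterSet | None = None) -> TmModel:
    """The shipped model: constants calibrated on the packaged anchors."""
    path = resources.files("itspcr.data") / "tm_calibration.yaml"
    cfg = yaml.safe_load(path.open())
    return TmModel(params or load_nn_params(),
                   monovalent_salt=float(cfg["monovalent_salt"]),
                   strand_concentration=float(cfg["strand_concentration"]),
                   salt_correction=str(cfg["salt_correction"]))


def shipped_anchors() -> list[tuple[str, float]]:
    """Anchor (primer sequence, Tm °C) pairs used for the shipped constants."""
    path = resources.files("itspcr.data") / "tm_calibration.yaml"
    cfg = yaml.safe_load(path.open())
    return [(a["sequence"], float(a["tm"])) for a in cfg["anchors"]]


def tm_mismatch_profile(primer: str, hits: list[str], model: TmModel,
                        options=None):
    """Group target windows by mismatch count; mean ± sd of duplex Tm.

    ``hits`` are target windows (5'→3', the strand the primer anneals
    to). Mismatch counts follow the amplification engine's rules; windows
    rejected by the 3'-tail rule are excluded and counted separately.
    Returns a DataFrame indexed by mismatch count with columns
    ``n``, ``mean_tm``, ``sd_tm`` (sd is NaN for singleton groups);
    empty groups are simply absent.
    """
    import pandas as pd

    from .pcr_engine import REJECT, AmplifyOptions, count_mismatches

    options = options or AmplifyOptions(max_mismatch=len(primer) - 3)
    groups: dict[int, list[float]] = {}
    rejected = 0
    for window in hits:
        site = reverse_complement(window.upper())
        count = count_mismatches(primer, site, options)
        if count is REJECT:
            rejected += 1
            continue
        groups.setdefault(count, []).append(duplex_tm(primer, window, model))
    rows = []
    for k in sorted(groups):
        vals = np.asarray(groups[k])
        rows.append({"mismatches": k, "n": len(vals),
                     "mean_tm": float(vals.mean()),
                     "sd_tm": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")})
    out = pd.DataFrame(rows, columns=["mismatches", "n", "mean_tm", "sd_tm"])
    out.attrs["rejected"] = rejected
    return out.set_index("mismatches")
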