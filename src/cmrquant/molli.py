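"""MOLLI acquisition schemes and inversion-time schedules.

A MOLLI (modified Look-Locker inversion recovery) acquisition collects
several inversion-prepared single-shot images over consecutive heartbeats.
A scheme string such as ``5(3)3`` means: one inversion followed by 5 images
on 5 consecutive heartbeats, 3 recovery heartbeats, then a second inversion
followed by 3 images.  Within one inversion group the effective inversion
times are ``ti_min + k * RR`` for image index ``k``, where RR is the cardiac
interval.  At the high heart rates of small primates (~150 bpm, RR ~400 ms)
the number of recovery beats is increased to let magnetisation recover; the
recovery-beat counts are therefore a free field of the scheme.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class MOLLIScheme:
    """A MOLLI sampling scheme.

    Parameters
    ----------
    groups:
        Ordered ``(images_per_inversion, recovery_beats)`` pairs, one per
        inversion.  The trailing group's recovery count is conventionally 0.
    rr_interval:
        Cardiac RR interval in ms (spacing of TIs within a group).
    ti_min:
        Minimum inversion time of each group, ms; one entry per group.
    """

    groups: tuple[tuple[int, int], ...]
    rr_interval: float = 400.0
    ti_min: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ti_min is None:
            # default vendor-style minima: 100 ms for the first inversion,
            # staggered +80 ms per later inversion (100/180/260/...) so that
            # groups sample distinct effective TIs
            tis = [100.0 + 80.0 * g for g in range(len(self.groups))]
            object.__setattr__(self, "ti_min", tuple(tis))
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))
        object.__setattr__(self, "ti_min", tuple(float(t) for t in self.ti_min))
        if not self.groups:
            raise ValueError("scheme needs at least one inversion group")
        if any(n < 1 or r < 0 for n, r in self.groups):
            raise ValueError("images_per_inversion must be >= 1 and recovery_beats >= 0")
        if self.rr_interval <= 0:
            raise ValueError("rr_interval must be positive")
        if len(self.ti_min) != len(self.groups):
            raise ValueError("need one ti_min per inversion group")
        if any(t <= 0 for t in self.ti_min):
            raise ValueError("ti_min values must be positive")

    @property
    def n_images(self) -> int:
        return sum(n for n, _ in self.groups)

    def __str__(self) -> str:
        out = []
        for i, (n, r) in enumerate(self.groups):
            out.append(str(n))
            if i < len(self.groups) - 1:
                out.append(f"({r})")
        return "".join(out)


def parse_molli_scheme(
    text: str, rr_interval: float = 400.0, ti_min: tuple[float, ...] | None = None
) -> MOLLIScheme:
    """Parse a scheme string like ``"5(3)3"`` or ``"4(1)3(1)2"``.

    Hyphenated CLI spellings (``5-3-3``) are accepted: odd positions are
    image counts, even positions recovery beats.
    """
    text = text.strip()
    if "-" in text:
        parts = [int(p) for p in text.split("-")]
        if len(parts) % 2 == 0:
            raise ValueError(f"cannot parse MOLLI scheme {text!r}")
        counts, recov = parts[0::2], parts[1::2] + [0]
        groups = tuple(zip(counts, recov))
        return MOLLIScheme(groups, rr_interval=rr_interval, ti_min=ti_min)
    tokens = re.findall(r"(\d+)(?:\((\d+)\))?", text)
    if not tokens or "".join(f"{a}({b})" if b else a for a, b in tokens) != text:
        raise ValueError(f"cannot parse MOLLI scheme {text!r}")
    groups = tuple((int(n), int(r) if r else 0) for n, r in tokens)
    return MOLLIScheme(groups, rr_interval=rr_interval, ti_min=ti_min)


def molli_ti_schedule(scheme: MOLLIScheme) -> list[tuple[float, int]]:
    """Effective inversion times of a scheme, in acquisition order.

    Returns ``(TI_ms, inversion_group_index)`` pairs; group ``g`` contributes
    ``images_per_inversion[g]`` TIs at ``ti_min[g] + k * rr_interval``.
    """
    out: list[tuple[float, int]] = []
    for g, (n_img, _recov) in enumerate(scheme.groups):
        for k in range(n_img):
            out.append((scheme.ti_min[g] + k * scheme.rr_interval, g))
    return out


#: default pre-contrast scheme (native T1)
SCHEME_PRE = parse_molli_scheme("5(3)3")
#: default post-contrast scheme
SCHEME_POST = parse_molli_scheme("4(1)3(1)2")
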