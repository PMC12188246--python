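"""Enumeration and screening of partially specified topologies.

A topology may leave regulatory signs ambiguous ("?" edges) and a set of
nodes may have undetermined diffusibility.  :func:`enumerate_completions`
expands the Cartesian product of the concrete choices;
:func:`screen_completions` runs the seeded parameter search on every
completion and tabulates which completions admit Turing instabilities.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import replace
from typing import Iterable, Sequence

import pandas as pd

from .network import Interaction, NetworkTopology, Node
from .search import SearchSpec, sample_turing_parameters

DEFAULT_COMPLETION_CAP = 4096

#: diffusion coefficient given to a node toggled diffusible that had none
DEFAULT_TOGGLED_DIFFUSION = 1.0


def enumerate_completions(
    t: NetworkTopology,
    vary_diffusibility: Iterable[str] = (),
    cap: int = DEFAULT_COMPLETION_CAP,
) -> list[NetworkTopology]:
    """All concrete completions of ambiguous signs and varied diffusibility.

    Each ambiguous edge takes sign +1 or -1 (arrow existence is never varied;
    deleting an arrow is a config edit, not an ambiguity), and each node in
    ``vary_diffusibility`` is tried both diffusible and not.  Order is
    deterministic: sign tuples vary fastest, in edge-list order, with +1
    before -1; diffusibility choices follow, diffusible-first.
    """
    vary = list(vary_diffusibility)
    for name in vary:
        t.index(name)  # raises KeyError for unknown nodes
    ambiguous = t.ambiguous_edges
    count = 2 ** (len(ambiguous) + len(vary))
    if count > cap:
        raise ValueError(
            f"{count} completions (2^{len(ambiguous)} signs x 2^{len(vary)} "
            f"diffusibility) exceed the cap of {cap}"
        )
    if not ambiguous and not vary:
        return [t]

    completions = []
    sign_choices = itertools.product(*([(1, -1)] * len(ambiguous)))
    for signs in sign_choices:
        resolved = {
            (e.source, e.target): s for e, s in zip(ambiguous, signs)
        }
        edges = tuple(
            replace(e, sign=resolved[(e.source, e.target)])
            if (e.source, e.target) in resolved
            else e
            for e in t.interactions
        )
        for flags in itertools.product(*([(True, False)] * len(vary))):
            toggled = dict(zip(vary, flags))
            nodes = []
            for node in t.nodes:
                if node.name in toggled:
                    diff = toggled[node.name]
                    coeff = (
                        (node.default_diffusion or DEFAULT_TOGGLED_DIFFUSION)
                        if diff
                        else 0.0
                    )
                    nodes.append(
                        replace(node, diffusible=diff, default_diffusion=coeff)
                    )
                else:
                    nodes.append(node)
            label_parts = []
            if signs:
                label_parts.append(
                    "s" + "".join("p" if s > 0 else "m" for s in signs)
                )
            if flags:
                label_parts.append(
                    "d" + "".join("y" if f else "n" for f in flags)
                )
            suffix = "_".join(label_parts)
            completions.append(
                replace(
                    t,
                    id=f"{t.id}__{suffix}",
                    nodes=tuple(nodes),
                    interactions=edges,
                )
            )
    return completions


def screen_completions(
    completions: Sequence[NetworkTopology], spec: SearchSpec
) -> pd.DataFrame:
    """Run the parameter search on every completion and tabulate the hits.

    ``spec``'s ranges and sample budget apply to every completion; each
    completion samples from an independent substream whose seed offsets
    ``spec.seed`` by a stable hash of the completion's canonical
    serialization, so a permutation of the completion list does not change
    any completion's result.  The table is sorted by hit count descending,
    ties by list order.
    """
    from .io import canonical_json, topology_to_dict

    rows = []
    for k, completion in enumerate(completions):
        offset = zlib.crc32(canonical_json(topology_to_dict(completion)).encode())
        sub = replace(spec, topology=completion, seed=(spec.seed + offset) % 2**31)
        result = sample_turing_parameters(sub)
        best_growth = (
            max(h.classification.dispersion.lambda_max for h in result.hits)
            if result.hits
            else float("nan")
        )
        signs = {
            f"{e.source}->{e.target}": ("+" if e.sign > 0 else "-")
            for e in completion.interactions
        }
        rows.append(
            {
                "completion_id": completion.id,
                "enumeration_index": k,
                "sign_assignment": "".join(signs.values()),
                "diffusibility_assignment": "".join(
                    "y" if n.diffusible else "n" for n in completion.nodes
                ),
                "hits": len(result.hits),
                "best_growth": best_growth,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["hits", "enumeration_index"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
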