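"""In-silico germline reversion of predicted-toxic light chains.

Somatic mutations of a toxic sequence are ranked by the best
information-gain rank among the features they participate in (the AMP
column at their position and any MAP/DAP contact pair containing it), and
reverted one at a time to the germline residue, re-encoding and
re-predicting after each step, until the predicted phenotype flips to
non-toxic or the candidates are exhausted.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .feature_extraction import FeatureMatrix, assemble_matrix
from .germline_align import NumberedSequence, SMutEncoding, encode_smut
from .io_formats import MISSING
from .ml_harness import RankedFeature, TrainedModel
from .structure_contacts import ContactMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReversionStep:
    position: int
    from_aa: str
    to_germline_aa: str
    driving_feature: str | None
    confidence_before: float
    confidence_after: float


@dataclass(frozen=True)
class ReversionPlan:
    sequence_id: str
    steps: tuple[ReversionStep, ...]
    final_label: str
    exhausted: bool

    def to_json(self) -> str:
        return json.dumps({
            "sequence_id": self.sequence_id,
            "final_label": self.final_label,
            "exhausted": self.exhausted,
            "steps": [{
                "position": s.position, "from": s.from_aa, "to": s.to_germline_aa,
                "driving_feature": s.driving_feature,
                "confidence_before": s.confidence_before,
                "confidence_after": s.confidence_after,
            } for s in self.steps],
        }, indent=1)


def rank_sm_candidates(encoding: SMutEncoding,
                       ranked_features: Sequence[RankedFeature]
                       ) -> list[tuple[int, int | None]]:
    """Order the encoding's somatic mutations by feature importance.

    Each SM is scored by the smallest (best) general rank among ranked
    features whose positions include it; SMs touching no ranked feature
    sort last.  Ties break by position index.  Returns
    ``[(position, best_rank_or_None), ...]``.
    """
    sms = encoding.sm_positions()
    best: dict[int, int | None] = {p: None for p in sms}
    for feat in ranked_features:
        for p in feat.descriptor.positions:
            if p in best and (best[p] is None or feat.general_rank < best[p]):
                best[p] = feat.general_rank
    return sorted(best.items(),
                  key=lambda kv: (kv[1] if kv[1] is not None else math.inf, kv[0]))


def _score_encoding(encoding: SMutEncoding, model: TrainedModel,
                    contact_map: ContactMap | None,
                    position_universe: Sequence[int]) -> float:
    families = tuple(dict.fromkeys(d.family for d in model.descriptors.values()))
    matrix = assemble_matrix([encoding], families, contact_map=contact_map,
                             position_universe=position_universe)
    return float(model.score(matrix.data)[0])


def greedy_revert(encoding: SMutEncoding, germline: NumberedSequence,
                  model: TrainedModel,
                  ranked_features: Sequence[RankedFeature],
                  position_universe: Sequence[int],
                  contact_map: ContactMap | None = None,
                  max_steps: int | None = None) -> ReversionPlan:
    """Revert SMs one at a time, best-ranked first, until predicted non-toxic.

    A sequence already predicted nox yields a no-op plan.  Each step sets
    the mutated position back to the germline residue; the plan records the
    driving feature and the confidence before and after.  ``exhausted`` is
    true when every SM was reverted without flipping the label.
    """
    conf = _score_encoding(encoding, model, contact_map, position_universe)
    if conf < model.threshold:
        return ReversionPlan(encoding.sequence_id, (), "nox", False)

    feature_by_pos: dict[int, RankedFeature] = {}
    for r in ranked_features:  # ascending rank: first seen is the best
        for p in r.descriptor.positions:
            feature_by_pos.setdefault(p, r)
    tokens = dict(encoding.token_by_position)
    steps: list[ReversionStep] = []
    current = encoding
    limit = max_steps if max_steps is not None else len(encoding.sm_positions())
    while len(steps) < limit:
        candidates = rank_sm_candidates(current, ranked_features)
        if not candidates:
            break
        pos, _rank = candidates[0]
        from_aa = tokens[pos]
        to_aa = germline.residue_by_position[pos]
        tokens[pos] = "X"
        current = SMutEncoding(current.sequence_id, dict(tokens),
                               current.germline_id)
        new_conf = _score_encoding(current, model, contact_map, position_universe)
        driving = feature_by_pos.get(pos)
        steps.append(ReversionStep(pos, from_aa, to_aa,
                                   driving.descriptor.name if driving else None,
                                   conf, new_conf))
        logger.info("reverted %s position %d (%s->%s): confidence %.3f -> %.3f",
                    encoding.sequence_id, pos, from_aa, to_aa, conf, new_conf)
        conf = new_conf
        if conf < model.threshold:
            return ReversionPlan(encoding.sequence_id, tuple(steps), "nox", False)
    exhausted = not current.sm_positions()
    return ReversionPlan(encoding.sequence_id, tuple(steps), "tox", exhausted)
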