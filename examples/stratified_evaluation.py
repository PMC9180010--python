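"""Stratified accuracy reporting by patient metadata (age group, gender).

Trains a reduced network briefly on a small synthetic corpus, then
prints per-stratum mIoU/per-class-IoU tables in the standard column
order (mIoU first, then the nine foreground classes).

Run:  python examples/stratified_evaluation.py
"""

import tempfile

from mvdnet import MVDNetSpec, TrainConfig, build_mvdnet, evaluate, train
from mvdnet.metrics import report_to_tsv
from mvdnet.synth import SceneConfig, generate_corpus

with tempfile.TemporaryDirectory() as d:
    corpus = generate_corpus(SceneConfig(width=64, height=64), 16, 2, 6, 21, d)
    spec = MVDNetSpec(stage_channels=(8, 12, 16), depths=(1, 2, 2))
    net = build_mvdnet(spec, seed=2)
    train(net, corpus, TrainConfig(batch_size=4, epochs=8, crop=64, seed=2),
          validate_each_epoch=False)

    for key in ("age_group", "gender"):
        report = evaluate(net, corpus.samples("test"), corpus.normalization,
                          schema=corpus.schema, group_key=key)
        print(report_to_tsv(report, key))

print("Rows are strata; '-' marks classes absent from a stratum")
print("(empty union), which are excluded from that stratum's mean.")
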