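#!/usr/bin/env python
"""Generate the reference synthetic study dataset.

Creates the 40-word multimorphemic lexicon (20 stems x 2 suffixes), its
ground-truth segmentation, structured segment vectors, and simulated evoked
responses with signal confined to 350-500 ms at SNR 5, and writes everything
under results/data/.
"""

import dataclasses
from pathlib import Path

from subdecode import io as sio
from subdecode.experiments import DISSOCIATION_CONFIG
from subdecode.segmentation import SegmentationScheme, build_lexicon, write_segmentation_lexicon
from subdecode.embedding import write_vectors
from subdecode.synthetic import make_dataset

SEED = 1

out = Path("results/data")
out.mkdir(parents=True, exist_ok=True)

config = dataclasses.replace(DISSOCIATION_CONFIG, seed=SEED)
epochs, truth = make_dataset(config)

sio.write_epochs_h5(epochs, out / "epochs.h5")
(out / "words.txt").write_text("\n".join(truth.words) + "\n", encoding="utf-8")
write_segmentation_lexicon(truth.lexicon, out / "segmentation_true.tsv")
for k in (1, 2, 3):
    lex = build_lexicon(truth.words, SegmentationScheme(name="ngram", k=k))
    write_segmentation_lexicon(lex, out / f"segmentation_{k}gram.tsv")
rand = build_lexicon(truth.words, SegmentationScheme(name="random", seed=SEED + 101))
write_segmentation_lexicon(rand, out / "segmentation_random.tsv")
write_vectors(truth.store, out / "segments.vec")
sio.write_json_summary(
    {"n_words": len(truth.words), "n_sensors": config.n_sensors,
     "sfreq_hz": config.sfreq, "snr": config.snr,
     "effect_window_s": list(config.effect_window)},
    out / "ground_truth.json",
    config=dataclasses.asdict(config),
)

print(f"wrote {len(truth.words)} words, epochs {epochs.data.shape} -> {out}/")
print(f"segment types: {len(truth.store)} (stems + suffixes)")
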