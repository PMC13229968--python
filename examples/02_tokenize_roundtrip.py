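"""Tokenize a plant to integer IDs and decode it back, losslessly.

A plant becomes one flat sequence: SOS, a <META> block (width, height,
vegetation fraction), a 4-token plant header (base rotation + age), then
organ tokens each followed by their quantized parameters, EOS. Decoding
reverses it exactly; the only information lost is sub-grid parameter
precision, and a second round-trip is token-identical.
"""

from plantarch import (
    build_vocabulary, bounding_metadata, detokenize, generate_plant,
    reconstruct_geometry, tokenize_architecture,
)
from plantarch.tokenizer import human_tokens

vocab = build_vocabulary()
plant = generate_plant(seed=0, age_days=10)
meta = bounding_metadata(reconstruct_geometry(plant), window_m=2.0)

seq = tokenize_architecture(plant, meta, vocab)
print(f"sequence length: {len(seq)} tokens")
print("first 20 token IDs:", " ".join(map(str, seq.ids[:20])))
print("readable form:     ", " ".join(human_tokens(seq, vocab)[:20]))

decoded, decoded_meta = detokenize(seq, vocab)
seq2 = tokenize_architecture(decoded, decoded_meta, vocab)
print(f"decoded plant: {len(decoded.shoots)} shoots, "
      f"{sum(len(s.phytomers) for s in decoded.shoots)} phytomers")
print("second round-trip token-exact:", seq2.ids == seq.ids)
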