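2026-10-01 01:48:47,063 rohscan.pipeline INFO rohscan 0.1.0
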