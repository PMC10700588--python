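03501ef6ff117f30fb448ebae01e502e3b2b556645101415748a518a0d6b398c
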