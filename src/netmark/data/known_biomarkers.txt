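miR-155-5p
miR-196a-5p
miR-218-5p
miR-143-3p
miR-182-5p
miR-650
miR-141-3p
miR-29c-3p
miR-23b-3p
miR-10b-5p
miR-21-5p
miR-126-3p
miR-451a
miR-25-3p
miR-145-5p
miR-210
miR-142-3p
miR-29b-3p
miR-590-5p
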