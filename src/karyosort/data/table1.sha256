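f900bbb8be4c0e32ba884a221af09af0be50fcf984bdc82f3d2905f8c4c3df31
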