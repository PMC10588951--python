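>human_alphaN_101-175 synthetic stand-in segment (not the biological sequence)
SSVQVKELLENIKSMKAEIEQLKNQLKEMQAELESLEAKIRQMKTKLKNLKAKIRNIQTDLKQLRNDVRNMKAQL
>mouse_alphaN_98-172 synthetic stand-in segment (not the biological sequence)
SSVQLKELLENIKTMRAEIENLKNQLKEMQAELESLESKIRQLKTKIRNLKAKVKNIQTELRQLRNDVRNLKAQL
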