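name,kind,cereal,aliases
beef,animal,no,
egg,animal,no,chicken eggs;eggs;chicken egg
salmon,animal,no,
cheese,animal,no,
bread,plant,no,
pasta,plant,no,
rice,plant,yes,
wheat,plant,yes,
maize,plant,yes,corn
potato,plant,no,potatoes
cabbage,plant,no,
carrot,plant,no,carrots
apple,plant,no,apples
beans,plant,no,bean
peanuts,plant,no,peanut;groundnut
olive oil,plant,no,olive_oil
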