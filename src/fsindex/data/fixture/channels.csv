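channel_name,size_class
hypermarket,large
supermarket,large
shopping_mall,large
wholesale_market,large
chain_store,medium
vegetable_market,medium
specialty_store,medium
farm_market,medium
online_platform,medium
restaurant,medium
grocery,small
street_vendor,small
canteen,small
bakery,small
butcher_shop,small
convenience_store,small
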